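"""DPI waveform, laminar surrogate fields, gradients and hand-off."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from fiberdep.flow import (ConstantWaveform, LobarSplit, WaveformError,
                           handoff_scale, handoff_waveform, make_dpi_waveform,
                           poiseuille_field, simple_shear_field)
from fiberdep.geometry import (build_bronchial_tree, build_straight_tube,
                               build_upper_surrogate)


@pytest.fixture(scope="module")
def waveform():
    return make_dpi_waveform()


@pytest.fixture(scope="module")
def upper_field(waveform):
    return poiseuille_field(build_upper_surrogate(), waveform, LobarSplit())


@pytest.fixture(scope="module")
def tree_field(upper_field):
    tree = build_bronchial_tree()
    return poiseuille_field(tree, handoff_waveform(upper_field, tree))


class TestDPIWaveform:
    def test_integral_equals_tidal_volume(self, waveform):
        assert waveform.integral() == pytest.approx(2.95, rel=1e-6)

    def test_boundary_values_vanish(self, waveform):
        assert waveform(0.0) == 0.0
        assert waveform(3.0) == pytest.approx(0.0, abs=1e-12)

    def test_peak_equals_pifr_on_plateau(self, waveform):
        t = np.linspace(0, 3, 2001)
        q = waveform(t)
        assert q.max() == pytest.approx(90.0)
        assert waveform(1.0) == pytest.approx(90.0)

    def test_plateau_end_closed_form(self, waveform):
        # 0.5*P*t_r + P*(t_h - t_r) + 0.5*P*(T - t_h) = TV with P = 1.5 L/s
        assert waveform.plateau_end == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_infeasible_volume_rejected(self):
        with pytest.raises(WaveformError, match="infeasible"):
            make_dpi_waveform(tidal_volume=10.0)
        with pytest.raises(WaveformError, match="infeasible"):
            make_dpi_waveform(tidal_volume=0.5)

    def test_integral_by_independent_quadrature(self, waveform):
        val, _ = quad(lambda s: waveform(s) / 60.0, 0, 3, limit=300)
        assert val == pytest.approx(waveform.tidal_volume, rel=1e-6)

    def test_bolus_window_inside_inspiration(self, waveform):
        b0, b1 = waveform.bolus_window
        assert 0 <= b0 < b1 <= waveform.duration
        assert (b0, b1) == (0.45, 0.6)


class TestPoiseuilleField:
    def test_centerline_twice_mean(self, upper_field):
        dom = upper_field.domain
        p = dom.inlet_origin + 0.5 * dom.lengths[0] * dom.dirs[0]
        u = upper_field.velocity(p, 1.0)
        assert np.linalg.norm(u) == pytest.approx(
            2.0 * upper_field.inlet_mean_velocity(1.0), rel=1e-12)

    def test_no_slip_at_wall_adjacent_points(self, upper_field):
        # the speed vanishes with the distance to the union-lumen wall
        dom = upper_field.domain
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 20:
            i = rng.integers(0, dom.n_segments)
            z = rng.uniform(0.3, 0.7) * dom.lengths[i]
            Rz = dom.local_radius(np.array([z]), np.array([i]))[0]
            e1 = np.cross(dom.dirs[i], [0.6, -0.64, 0.48])
            e1 /= np.linalg.norm(e1)
            phi = rng.uniform(0, 2 * math.pi)
            e = math.cos(phi) * e1 + math.sin(phi) * np.cross(dom.dirs[i], e1)
            p = dom.origins[i] + z * dom.dirs[i] + 0.9999 * Rz * e
            wd = dom.wall_distance(p)
            if not (0.0 <= wd <= 2e-4 * Rz):
                continue  # interior of an overlapping neighbour segment
            u = upper_field.velocity(p, 1.0)
            umax = 2 * np.abs(upper_field._coef).max() \
                * upper_field.waveform.q_si(1.0)
            assert np.linalg.norm(u) < 5.0 * umax * wd / Rz + 1e-9
            checked += 1

    @pytest.mark.parametrize("which", ["upper", "tree"])
    def test_gradient_matches_finite_differences(self, which, upper_field,
                                                 tree_field):
        fld = upper_field if which == "upper" else tree_field
        dom = fld.domain
        rng = np.random.default_rng(3)
        h = 1e-8
        checked = 0
        while checked < 50:
            i = rng.integers(0, dom.n_segments)
            z = rng.uniform(0.02, 0.95) * dom.lengths[i]
            # skip the non-smooth loci: cone boundaries and miter planes
            cs, cl = dom.cone_start[i], dom.cone_len[i]
            if min(abs(z - cs), abs(z - cs - cl)) < 0.02 * dom.lengths[i]:
                continue
            if z < cs + 0.02 * dom.lengths[i]:
                continue
            Rz = dom.local_radius(np.array([z]), np.array([i]))[0]
            r = rng.uniform(0.05, 0.8) * Rz
            e1 = np.cross(dom.dirs[i], [0.2, 0.9, -0.39])
            e1 /= np.linalg.norm(e1)
            phi = rng.uniform(0, 2 * math.pi)
            e = math.cos(phi) * e1 + math.sin(phi) * np.cross(dom.dirs[i], e1)
            p = dom.origins[i] + z * dom.dirs[i] + r * e
            if dom.wall_distance(p) < 0.1 * Rz:
                continue
            G = fld.gradient(p, 1.0)
            num = np.zeros((3, 3))
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = h
                num[:, j] = (fld.velocity(p + dp, 1.0)
                             - fld.velocity(p - dp, 1.0)) / (2 * h)
            scale = max(np.abs(G).max(), 1e-9)
            assert np.abs(num - G).max() / scale < 1e-4
            checked += 1

    def test_flux_conserved_at_bifurcations(self, tree_field):
        # parent flux equals the sum of child fluxes at every junction
        dom = tree_field.domain
        for i in range(dom.n_segments):
            kids = [int(c) for c in dom.children[i] if c >= 0]
            if not kids:
                continue
            qp = tree_field.segment_flux(i, 1.0)
            qc = sum(tree_field.segment_flux(k, 1.0) for k in kids)
            assert qc == pytest.approx(qp, rel=1e-10)

    def test_flux_integral_mid_segment(self, tree_field):
        # numerically integrate the axial profile over a mid-segment disc
        dom = tree_field.domain
        i = 0
        z = 0.7 * dom.lengths[i]
        R = dom.radii[i]
        d = dom.dirs[i]
        e1 = np.cross(d, [1.0, 0, 0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        nr, nphi = 400, 64
        rr = (np.arange(nr) + 0.5) / nr * R
        flux = 0.0
        for phi in np.linspace(0, 2 * math.pi, nphi, endpoint=False):
            pts = (dom.origins[i] + z * d
                   + rr[:, None] * (math.cos(phi) * e1
                                    + math.sin(phi) * e2)[None, :])
            u = tree_field.velocity(pts, 1.0, np.full(nr, i))
            flux += np.sum((u @ d) * rr) * (R / nr) * (2 * math.pi / nphi)
        assert flux == pytest.approx(tree_field.segment_flux(0, 1.0),
                                     rel=1e-3)

    def test_lobar_outflow_fractions(self, upper_field):
        # time-integrated outflow per lobe / total equals the split
        dom = upper_field.domain
        split = upper_field.split
        total = quad(lambda s: upper_field.waveform.q_si(s), 0, 3,
                     points=[0.4, 4 / 3], limit=200)[0]
        for i in dom.outlet_segments():
            tok = dom.exit_labels[i]
            qi = quad(lambda s: upper_field.fractions[i]
                      * upper_field.waveform.q_si(s), 0, 3,
                      points=[0.4, 4 / 3], limit=200)[0]
            assert qi / total == pytest.approx(split.fraction(tok), abs=1e-6)

    def test_negative_lobar_fraction_rejected(self):
        with pytest.raises(Exception, match="positive|sum"):
            LobarSplit({"LU": -5.0, "LL": 51.0, "RU": 14.0, "RM": 7.0,
                        "RL": 33.0})


class TestHandoff:
    def test_identity_handoff(self):
        tube = build_straight_tube(5e-3, 0.1)
        f = poiseuille_field(tube, make_dpi_waveform())
        scale, delay = handoff_scale(f, tube, flow_fraction=1.0)
        assert scale == pytest.approx(1.0)
        vol = tube.volume()
        assert delay == pytest.approx(vol / f.waveform.mean_flow_si())

    def test_half_area_half_flow_gives_unit_scale(self):
        tube = build_straight_tube(5e-3, 0.1)
        small = build_straight_tube(5e-3 / math.sqrt(2.0), 0.1)
        f = poiseuille_field(tube, make_dpi_waveform())
        scale, _ = handoff_scale(f, small, flow_fraction=0.5)
        assert scale == pytest.approx(1.0, rel=1e-12)

    def test_delay_matches_fill_time(self, upper_field):
        tree = build_bronchial_tree()
        _, delay = handoff_scale(upper_field, tree)
        vol = upper_field.domain.volume()
        qbar = 2.95e-3 / 3.0
        assert delay == pytest.approx(vol / qbar, rel=1e-12)
        # ~0.1 L at a 59 L/min mean flow fills in about 0.1 s
        assert 0.08 < delay < 0.12

    def test_no_flow_signalled(self):
        tube = build_straight_tube(5e-3, 0.1)
        f = poiseuille_field(tube, ConstantWaveform(0.0))
        with pytest.raises(Exception, match="no flow"):
            handoff_scale(f, tube)

    def test_tree_waveform_scaling(self, upper_field):
        tree = build_bronchial_tree()
        wf = handoff_waveform(upper_field, tree)
        scale, _ = handoff_scale(upper_field, tree)
        v_up = upper_field.waveform.q_si(1.0) / upper_field.domain.inlet_area
        v_down = wf.q_si(1.0) / tree.inlet_area
        assert v_down / v_up == pytest.approx(scale, rel=1e-12)


class TestSimpleShear:
    def test_gradient_entry(self):
        f = simple_shear_field(10.0)
        G = f.gradient(np.zeros(3))
        assert G[0, 1] == 10.0
        assert np.count_nonzero(G) == 1

    def test_vorticity_magnitude(self):
        f = simple_shear_field(10.0)
        G = f.gradient(np.zeros(3))
        omega = np.array([G[2, 1] - G[1, 2], G[0, 2] - G[2, 0],
                          G[1, 0] - G[0, 1]])
        assert np.linalg.norm(omega) == pytest.approx(10.0)

    def test_rate_of_strain_eigenvalues(self):
        f = simple_shear_field(10.0)
        G = f.gradient(np.zeros(3))
        S = 0.5 * (G + G.T)
        ev = np.sort(np.linalg.eigvalsh(S))
        np.testing.assert_allclose(ev, [-5.0, 0.0, 5.0], atol=1e-12)


def test_reynolds_decreases_from_upper_inlet_to_tree_terminals(
        upper_field, tree_field):
    # order-of-magnitude chain at peak flow: the inlet Re (turbulent in
    # the anatomical problem) far exceeds the tree-entrance Re, which
    # decays monotonically to the terminal generations
    re_up = upper_field.reynolds(1.0)[0]
    tree = tree_field.domain
    re_tree = tree_field.reynolds(1.0)
    per_gen = [re_tree[tree.generations == g][0]
               for g in range(7, 17)]
    assert re_up > 4000
    assert re_up > per_gen[0]
    assert 100 < per_gen[0] < 1000
    assert np.all(np.diff(per_gen) < 0)
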