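"""DPI inhalation waveform and analytic laminar velocity fields.

The dry-powder-inhaler (DPI) maneuver is parameterised by its tidal volume
(TV, litres), peak inspiratory flow rate (PIFR, L/min) and inspiration
duration (s): a sin^2 ramp to the peak, a plateau whose end is solved in
closed form so the time integral equals TV, and a cosine decay back to
zero.  Defaults reproduce an adult DPI maneuver: TV = 2.95 L, PIFR =
90 L/min, 3 s inspiration, with the particle bolus injected between 0.45
and 0.6 s.

Velocity fields are analytic laminar (Poiseuille) profiles per tube
segment, scaled in time by the waveform and split across branches (equal
split at tree bifurcations, configurable lobar fractions at the
upper-surrogate outlets).  The fields stand in for the RANS solution of
the anatomical problem and are deliberately labelled surrogates: no
turbulence, no secondary flows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .geometry import (AirwayTree, LOBAR_TOKENS, SegmentedDomain,
                       UpperAirwaySurrogate)

__all__ = [
    "WaveformError",
    "FlowError",
    "DPIWaveform",
    "ScaledWaveform",
    "LobarSplit",
    "FlowField",
    "PoiseuilleField",
    "SimpleShearField",
    "make_dpi_waveform",
    "poiseuille_field",
    "handoff_scale",
    "handoff_waveform",
    "simple_shear_field",
]


class WaveformError(ValueError):
    pass


class FlowError(ValueError):
    pass


@dataclass(frozen=True)
class DPIWaveform:
    """Inlet flow-rate profile Q(t) of one DPI inspiration.

    ``Q(0) = Q(duration) = 0``, ``max Q = peak_flow`` on the plateau and
    the time integral equals ``tidal_volume``.
    """

    tidal_volume: float           # L
    peak_flow: float              # L/min
    duration: float               # s
    rise_time: float              # s
    plateau_end: float            # s, solved from the volume constraint
    bolus_window: tuple[float, float] = (0.45, 0.6)

    def __call__(self, t):
        """Flow rate in L/min at time ``t`` (s); vectorised."""
        t = np.asarray(t, dtype=float)
        P = self.peak_flow
        tr, th, T = self.rise_time, self.plateau_end, self.duration
        ramp = P * np.sin(0.5 * math.pi * np.clip(t, 0, tr) / tr) ** 2
        decay_phase = np.clip((t - th) / max(T - th, 1e-300), 0.0, 1.0)
        decay = P * 0.5 * (1.0 + np.cos(math.pi * decay_phase))
        out = np.where(t < tr, ramp, np.where(t <= th, P, decay))
        out = np.where((t < 0) | (t > T), 0.0, out)
        return out if out.ndim else float(out)

    def q_si(self, t):
        """Volumetric flow rate in m^3/s."""
        q = self.__call__(t)
        return q * (1e-3 / 60.0)

    def integral(self, t0: float | None = None, t1: float | None = None) -> float:
        """Inhaled volume (L) by adaptive quadrature."""
        t0 = 0.0 if t0 is None else t0
        t1 = self.duration if t1 is None else t1
        pts = [p for p in (self.rise_time, self.plateau_end) if t0 < p < t1]
        val, _ = quad(lambda s: self.__call__(s) / 60.0, t0, t1,
                      points=pts, limit=200)
        return val

    def mean_flow_si(self) -> float:
        """Time-averaged volumetric flow over the inspiration, m^3/s."""
        return self.tidal_volume * 1e-3 / self.duration

    def to_csv(self, path, n: int = 601) -> None:
        """Two-column CSV export (t_s, Q_Lmin)."""
        t = np.linspace(0.0, self.duration, n)
        arr = np.column_stack([t, self.__call__(t)])
        np.savetxt(path, arr, delimiter=",", header="t_s,Q_Lmin",
                   comments="", fmt="%.9g")


def make_dpi_waveform(tidal_volume: float = 2.95,
                      peak_flow: float = 90.0,
                      duration: float = 3.0,
                      rise_time: float = 0.4,
                      bolus_window: tuple[float, float] = (0.45, 0.6),
                      ) -> DPIWaveform:
    """Construct the DPI waveform from its printed characteristics.

    The plateau end ``t_h`` solves
    ``P*t_r/2 + P*(t_h - t_r) + P*(T - t_h)/2 = TV`` with ``P`` the peak
    flow in L/s, giving ``t_h = 2*TV/P + t_r - T``.
    """
    if rise_time <= 0 or rise_time >= duration:
        raise WaveformError("rise_time must lie in (0, duration)")
    P = peak_flow / 60.0  # L/s
    if P * duration < tidal_volume:
        raise WaveformError("infeasible waveform: peak_flow * duration < TV")
    t_h = 2.0 * tidal_volume / P + rise_time - duration
    if not (rise_time <= t_h <= duration):
        raise WaveformError(
            "infeasible waveform: no plateau end in [rise_time, duration] "
            f"satisfies the volume constraint (got t_h = {t_h:.4g} s)")
    b0, b1 = bolus_window
    if not (0.0 <= b0 < b1 <= duration):
        raise WaveformError("bolus_window must lie within the inspiration")
    return DPIWaveform(tidal_volume, peak_flow, duration, rise_time, t_h,
                       (b0, b1))


@dataclass(frozen=True)
class ScaledWaveform:
    """A base waveform rescaled by a constant factor (inter-domain hand-off)."""

    base: DPIWaveform
    factor: float

    def __call__(self, t):
        return self.base(t) * self.factor

    def q_si(self, t):
        return self.base.q_si(t) * self.factor

    @property
    def duration(self) -> float:
        return self.base.duration

    @property
    def peak_flow(self) -> float:
        return self.base.peak_flow * self.factor

    @property
    def bolus_window(self):
        return self.base.bolus_window

    def mean_flow_si(self) -> float:
        return self.base.mean_flow_si() * self.factor


@dataclass(frozen=True)
class ConstantWaveform:
    """Steady flow rate; validation fixture (L/min)."""

    flow: float                  # L/min
    duration: float = math.inf
    bolus_window: tuple[float, float] = (0.0, 0.0)

    def __call__(self, t):
        return np.broadcast_to(self.flow, np.shape(t)).copy() \
            if np.ndim(t) else self.flow

    def q_si(self, t):
        q = self.__call__(t)
        return q * (1e-3 / 60.0)

    @property
    def peak_flow(self) -> float:
        return self.flow

    def mean_flow_si(self) -> float:
        return self.flow * (1e-3 / 60.0)


@dataclass(frozen=True)
class LobarSplit:
    """Ventilation fractions per lung lobe, in percent of inlet flow."""

    fractions: dict = field(default_factory=lambda: {
        "LU": 15.0, "LL": 31.0, "RU": 14.0, "RM": 7.0, "RL": 33.0})

    def __post_init__(self) -> None:
        missing = set(LOBAR_TOKENS) - set(self.fractions)
        if missing:
            raise FlowError(f"lobar split missing lobes {sorted(missing)}")
        vals = np.array([self.fractions[k] for k in LOBAR_TOKENS], dtype=float)
        if np.any(vals <= 0):
            raise FlowError("lobar fractions must all be positive")
        if abs(vals.sum() - 100.0) > 1e-9:
            raise FlowError(f"lobar fractions must sum to 100, got {vals.sum()}")

    def fraction(self, token: str) -> float:
        return self.fractions[token] / 100.0


class FlowField:
    """Abstract time-dependent velocity field with analytic gradients."""

    domain: SegmentedDomain | None = None

    def velocity(self, points, t, seg_idx=None):
        raise NotImplementedError

    def gradient(self, points, t, seg_idx=None):
        raise NotImplementedError

    def evaluate(self, points, t, seg_idx=None):
        return (self.velocity(points, t, seg_idx),
                self.gradient(points, t, seg_idx))


class PoiseuilleField(FlowField):
    """Per-segment parabolic (Poiseuille) profile scaled by the waveform.

    Each segment carries a fixed share of the inlet flow (its flow
    fraction); the axial profile is ``u(r) = 2*u_mean*(1 - (r/R)^2)`` with
    no-slip walls.  Within one segment-diameter downstream of a junction
    the flow direction is blended linearly from the parent axis to the
    child axis (smoothing the kink at bends and bifurcations); the
    magnitude always follows the local segment's parabolic profile so the
    per-branch flux assignment is preserved.
    """

    def __init__(self, domain: SegmentedDomain, waveform,
                 split: LobarSplit | str = "equal"):
        self.domain = domain
        self.waveform = waveform
        self.split = split
        self.fractions = self._solve_fractions()
        if np.any(self.fractions < 0):
            raise FlowError("negative flow assigned to a segment")
        A = math.pi * domain.radii ** 2
        # mean-velocity coefficient in the cylindrical part of a segment
        self._coef = self.fractions / A
        # flow within a segment's claim is parallel to the parent axis
        # upstream of the junction bisector (miter) plane, to the segment
        # axis between its own miter plane and those of its children, and
        # to a child's axis beyond that child's miter plane, so
        # streamlines kink at the planes (like flow in mitred elbows) and
        # never cross walls
        K = domain.child_table.shape[1]
        cm = np.zeros((domain.n_segments, K, 3))
        valid = domain.child_table >= 0
        cm[valid] = domain.miter_normal[domain.child_table[valid]]
        self._child_miter = cm                     # (S, K, 3)
        cd = np.zeros((domain.n_segments, K, 3))
        cd[valid] = domain.dirs[domain.child_table[valid]]
        self._child_dirs = cd

    def _solve_fractions(self) -> np.ndarray:
        dom = self.domain
        frac = np.ones(dom.n_segments)
        if isinstance(dom, UpperAirwaySurrogate):
            split = self.split
            for i, lab in enumerate(dom.labels):
                if lab in LOBAR_TOKENS:
                    if isinstance(split, LobarSplit):
                        frac[i] = split.fraction(lab)
                    else:
                        frac[i] = 1.0 / 5.0
        elif isinstance(dom, AirwayTree):
            if isinstance(self.split, LobarSplit):
                raise FlowError("bronchial tree outlets divide flow equally")
            level = dom.generations - dom.root_generation
            frac = 0.5 ** level.astype(float)
        return frac

    # -- evaluation --------------------------------------------------------
    def _frames(self, points, seg_idx):
        dom = self.domain
        z, rvec, r = dom.segment_frames(points, seg_idx)
        return z, rvec, r

    def velocity(self, points, t, seg_idx=None):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        seg_idx = self._resolve_segments(pts, seg_idx)
        u = self._velocity_impl(pts, t, seg_idx)
        return u[0] if np.asarray(points).ndim == 1 else u

    def gradient(self, points, t, seg_idx=None):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        seg_idx = self._resolve_segments(pts, seg_idx)
        g = self._gradient_impl(pts, t, seg_idx)
        return g[0] if np.asarray(points).ndim == 1 else g

    def evaluate(self, points, t, seg_idx=None):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        seg_idx = self._resolve_segments(pts, seg_idx)
        terms = self._frame_terms(pts, t, seg_idx)
        z, rvec = terms[0], terms[1]
        D = self._direction(z, rvec, seg_idx)
        return (self._velocity_from(terms, D),
                self._gradient_from(terms, D, seg_idx))

    def _resolve_segments(self, pts, seg_idx):
        if seg_idx is None:
            all_idx = np.arange(self.domain.n_segments)
            s = self.domain.signed_distance_to(pts[:, None, :],
                                               all_idx[None, :])
            return np.argmax(s, axis=1)
        return np.atleast_1d(np.asarray(seg_idx, dtype=int))

    def _frame_terms(self, pts, t, seg):
        """Common per-point quantities of the cone-flow construction.

        Within the junction blend zone (axial coordinate ``z`` in
        ``[0, ell]`` of a non-root segment) the wall radius tapers
        linearly from the parent radius to the segment radius; the
        self-similar parabolic profile in such a cone carries the exact
        mass-consistent radial velocity ``u_r = u_z * r * R'(z) / R(z)``,
        which funnels particles through contractions and spreads them in
        diffuser sections instead of sweeping them into junction faces.
        """
        dom = self.domain
        q = self.waveform.q_si(t)
        z, rvec, r = dom.segment_frames(pts, seg)
        ell = dom.cone_len[seg]
        cs = dom.cone_start[seg]
        par = dom.parent[seg]
        has_par = par >= 0
        par_s = np.where(has_par, par, seg)
        w = np.where(has_par, np.clip((z - cs) / ell, 0.0, 1.0), 1.0)
        R_c, R_b = dom.radii[seg], dom.base_radii[seg]
        in_cone = has_par & (z > cs) & (z < cs + ell)
        R = R_c + (R_b - R_c) * (1.0 - w)
        Rp = np.where(in_cone, (R_c - R_b) / ell, 0.0)   # dR/dz
        # mean velocity scales with the local cone area (flux conserved)
        umean = self.fractions[seg] * q / (math.pi * R ** 2)
        m = 2.0 * umean * np.maximum(1.0 - (r / R) ** 2, 0.0)
        return z, rvec, r, R, Rp, w, par_s, ell, umean, m, in_cone

    def _direction(self, z, rvec, seg):
        """Piecewise flow direction (see the class docstring): parent
        axis upstream of the own miter plane, child axis beyond a child
        miter plane, segment axis in between.  Constant within each
        region, so it contributes no smooth gradient term."""
        dom = self.domain
        d_c = dom.dirs[seg]
        par = dom.parent[seg]
        has_par = par >= 0
        d_p = dom.dirs[np.where(has_par, par, seg)]
        n = dom.miter_normal[seg]
        side = (z * np.einsum("ij,ij->i", d_c, n)
                + np.einsum("ij,ij->i", rvec, n))
        upstream = has_par & (side < 0.0)
        D = np.where(upstream[:, None], d_p, d_c)

        # beyond a child's miter plane (relative to this segment's far
        # junction point) the flow already runs along that child's axis
        w_end = ((z - dom.lengths[seg])[:, None] * d_c + rvec)  # (N, 3)
        cside = np.einsum("nj,nkj->nk", w_end, self._child_miter[seg])
        k_best = np.argmax(cside, axis=1)
        rows = np.arange(len(seg))
        past = cside[rows, k_best] > 0.0
        if np.any(past):
            D = np.where(past[:, None],
                         self._child_dirs[seg, k_best], D)
        return D

    def _velocity_impl(self, pts, t, seg):
        terms = self._frame_terms(pts, t, seg)
        D = self._direction(terms[0], terms[1], seg)
        return self._velocity_from(terms, D)

    def _gradient_impl(self, pts, t, seg):
        terms = self._frame_terms(pts, t, seg)
        D = self._direction(terms[0], terms[1], seg)
        return self._gradient_from(terms, D, seg)

    def _velocity_from(self, terms, D):
        z, rvec, r, R, Rp, w, par_s, ell, umean, m, in_cone = terms
        c_rad = m * Rp / R                       # radial funnel coefficient
        return m[:, None] * D + c_rad[:, None] * rvec

    def _gradient_from(self, terms, D, seg):
        dom = self.domain
        z, rvec, r, R, Rp, w, par_s, ell, umean, m, in_cone = terms
        d_c = dom.dirs[seg]
        inside = (1.0 - (r / R) ** 2) > 0.0

        # grad m = -(4 umean / R^2) rvec + dm/dz d_c
        dm_dz = np.where(in_cone & inside,
                         (4.0 * umean * Rp / R) * (2.0 * (r / R) ** 2 - 1.0),
                         0.0)
        radial_coef = np.where(inside, -4.0 * umean / R ** 2, 0.0)
        grad_m = radial_coef[:, None] * rvec + dm_dz[:, None] * d_c

        out = D[:, :, None] * grad_m[:, None, :]

        # radial funnel term u_rad = c(r, z) rvec with c = m R'/R
        c_rad = m * Rp / R
        if np.any(in_cone):
            grad_c = ((Rp / R)[:, None] * grad_m
                      - (m * (Rp / R) ** 2)[:, None] * d_c)
            P_perp = (np.eye(3)[None, :, :]
                      - d_c[:, :, None] * d_c[:, None, :])
            out = (out + rvec[:, :, None] * grad_c[:, None, :]
                   + c_rad[:, None, None] * P_perp)
        return out

    # -- diagnostics -------------------------------------------------------
    def inlet_mean_velocity(self, t):
        """Mean inlet velocity u_bar(t), m/s."""
        return self.waveform.q_si(t) * self._coef[0]

    @property
    def u0(self) -> float:
        """Maximal (centreline) inlet velocity at peak inhalation, m/s."""
        qmax = self.waveform.peak_flow * (1e-3 / 60.0)
        return 2.0 * qmax * self._coef[0]

    def reynolds(self, t, nu: float = 1.51e-5) -> np.ndarray:
        """Per-segment Reynolds number ``Re = u_mean * D / nu`` at time t."""
        q = self.waveform.q_si(t)
        return self._coef * q * 2.0 * self.domain.radii / nu

    def segment_flux(self, seg: int, t) -> float:
        """Volumetric flux assigned to one segment, m^3/s."""
        return float(self.fractions[seg] * self.waveform.q_si(t))


class SimpleShearField(FlowField):
    """Unbounded simple shear ``u = (gamma_dot * y, 0, 0)``; test fixture."""

    def __init__(self, shear_rate: float):
        self.shear_rate = float(shear_rate)
        self.domain = None

    def velocity(self, points, t=0.0, seg_idx=None):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.zeros_like(pts)
        u[:, 0] = self.shear_rate * pts[:, 1]
        return u[0] if np.asarray(points).ndim == 1 else u

    def gradient(self, points, t=0.0, seg_idx=None):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = np.zeros((len(pts), 3, 3))
        g[:, 0, 1] = self.shear_rate
        return g[0] if np.asarray(points).ndim == 1 else g


def poiseuille_field(domain: SegmentedDomain, waveform,
                     split: LobarSplit | str = "equal") -> PoiseuilleField:
    """Laminar per-branch parabolic field on ``domain`` driven by ``waveform``."""
    return PoiseuilleField(domain, waveform, split)


def simple_shear_field(shear_rate: float) -> SimpleShearField:
    """Constant-gradient validation field ``u = (shear_rate * y, 0, 0)``."""
    return SimpleShearField(shear_rate)


def handoff_scale(upstream: PoiseuilleField, downstream_domain: SegmentedDomain,
                  flow_fraction: float | None = None) -> tuple[float, float]:
    """Inter-domain hand-off: velocity scale factor and bolus delay.

    ``scale`` is the ratio of the time-averaged inlet mean velocity of the
    downstream domain to that of the upstream domain.  By default the
    downstream inlet velocity equals the average exit velocity over the
    upstream outlets (velocity continuity across the hand-off); passing
    ``flow_fraction`` instead assigns that share of the upstream flow to
    the downstream inlet.  ``delay`` is the time for the mean flow to fill
    the upstream lumen volume.
    """
    qbar = upstream.waveform.mean_flow_si()
    if qbar <= 0:
        raise FlowError("no flow: upstream waveform has zero mean flow")
    dom_up = upstream.domain
    v_up = qbar * upstream._coef[0]
    A_down = downstream_domain.inlet_area
    if flow_fraction is not None:
        v_down = flow_fraction * qbar / A_down
    else:
        outs = dom_up.outlet_segments()
        if not outs:
            raise FlowError("upstream domain has no outlets")
        v_down = float(np.mean([qbar * upstream._coef[i] for i in outs]))
    scale = v_down / v_up
    delay = dom_up.volume() / qbar
    return scale, delay


def handoff_waveform(upstream: PoiseuilleField,
                     downstream_domain: SegmentedDomain,
                     flow_fraction: float | None = None) -> ScaledWaveform:
    """Waveform for the downstream domain implied by the hand-off scaling.

    The downstream inlet mean velocity is ``scale`` times the upstream
    inlet mean velocity at every instant, i.e.
    ``Q_down(t) = scale * Q(t) * A_down / A_up``.
    """
    scale, _ = handoff_scale(upstream, downstream_domain, flow_fraction)
    factor = scale * downstream_domain.inlet_area / upstream.domain.inlet_area
    return ScaledWaveform(upstream.waveform, factor)
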