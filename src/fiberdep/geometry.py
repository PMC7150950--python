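"""Synthetic airway geometries with analytic wall-distance queries.

The package replaces anatomical CFD meshes with unions of straight
cylindrical tube segments: a symmetric dichotomous bronchial tree, a
generic upper-airway surrogate (mouth tube, laryngeal constriction, bend,
trachea, five lobar outlet branches), and a plain straight tube used by
validation fixtures.  Every domain supports three queries used by the
particle tracker:

* ``wall_distance`` -- signed distance to the nearest *lateral* wall
  (positive inside the lumen).  Inlet and outlet discs are open flow
  boundaries, not walls.
* ``locate_region`` -- deterministic region tag for a point, including
  ``"exited:<label>"`` for points swept past an outlet plane.
* ``inlet_seed_grid`` -- uniform Cartesian lattice clipped to the inlet
  disc, used to introduce particle boluses.

All quantities are SI (metres) in a right-handed frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "TubeSegment",
    "SegmentedDomain",
    "AirwayTree",
    "UpperAirwaySurrogate",
    "StraightTube",
    "SeedGrid",
    "build_bronchial_tree",
    "build_upper_surrogate",
    "build_straight_tube",
    "wall_distance",
    "locate_region",
    "inlet_seed_grid",
    "LOBAR_TOKENS",
]

LOBAR_TOKENS = ("LU", "LL", "RU", "RM", "RL")


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometry requests."""


@dataclass(frozen=True)
class TubeSegment:
    """One straight cylindrical airway segment."""

    origin: np.ndarray          # axis start, m
    direction: np.ndarray       # unit axis vector
    length: float               # m
    radius: float               # m
    generation: int             # generation label
    region: str                 # region tag token

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise GeometryError("segment radius and length must be positive")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise GeometryError("segment direction must be a unit vector")

    @property
    def end(self) -> np.ndarray:
        return self.origin + self.length * self.direction


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero vector cannot be normalised")
    return v / n


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle`` (rad)."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


class SegmentedDomain:
    """Union of cylindrical segments stored as flat numpy arrays.

    Attributes
    ----------
    origins, dirs : (S, 3) float arrays
    lengths, radii : (S,) float arrays
    generations : (S,) int array
    labels : list of region tags, one per segment
    parent : (S,) int array, -1 for the root
    children : (S, 2) int array, -1 where absent
    exit_labels : list, outlet label for segments whose far plane is an
        open outlet of the domain, else None
    gravity : (3,) unit vector
    """

    name = "domain"

    def __init__(self, origins, dirs, lengths, radii, generations, labels,
                 parent, children, exit_labels, gravity, frame_u=None,
                 carina_sharpness: float = 0.7):
        self.carina_sharpness = float(carina_sharpness)
        self.origins = np.asarray(origins, dtype=float)
        self.dirs = np.asarray(dirs, dtype=float)
        self.lengths = np.asarray(lengths, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.generations = np.asarray(generations, dtype=int)
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=int)
        self.children = np.asarray(children, dtype=int)
        self.exit_labels = list(exit_labels)
        self.gravity = _unit(gravity)
        self.frame_u = (np.asarray(frame_u, dtype=float)
                        if frame_u is not None else None)
        self.n_segments = len(self.lengths)
        # junction transition cones: over a blend length at the start of
        # each non-root segment the wall radius tapers linearly from the
        # parent radius to the segment radius, so bifurcation planes and
        # area changes present no flat annular faces to the flow
        self.base_radii = np.where(self.parent >= 0,
                                   self.radii[self.parent], self.radii)
        # transition-cone length: one diameter, extended by the junction
        # wedge depth when the segment is tilted against its parent
        tilt = np.zeros(self.n_segments)
        for i in range(self.n_segments):
            p = self.parent[i]
            if p >= 0:
                tilt[i] = math.acos(float(np.clip(
                    np.dot(self.dirs[i], self.dirs[p]), -1.0, 1.0)))
        self.tilt = tilt
        # junction transition cone: a stub at the parent radius spanning
        # the miter-plane wedge (so the taper only begins once the flow
        # has turned onto this segment's axis for every azimuth), then a
        # linear taper to the segment radius over one diameter
        self.cone_start = (self.base_radii
                           * np.tan(0.5 * np.minimum(tilt, 1.4)))
        self.cone_len = 2.0 * self.radii
        self.blend_len = self.cone_start + self.cone_len
        # a child's junction plane is perpendicular to the *child* axis, so
        # a bend leaves a wedge behind it that no child covers; the parent
        # keeps its lateral claim past its end plane by the wedge depth
        pad = np.zeros(self.n_segments)
        for i in range(self.n_segments):
            kids = [int(c) for c in self.children[i] if c >= 0]
            kids += [j for j in range(self.n_segments)
                     if self.parent[j] == i and j not in kids]
            if kids:
                tans = [math.tan(min(math.acos(np.clip(
                    np.dot(self.dirs[i], self.dirs[j]), -1, 1)), 1.4))
                    for j in kids]
                pad[i] = 1.05 * self.radii[i] * max(tans)
        self.axial_pad = pad
        # child table rebuilt from the parent array (K = max fan-out)
        kids_of = [[] for _ in range(self.n_segments)]
        for j in range(self.n_segments):
            if self.parent[j] >= 0:
                kids_of[self.parent[j]].append(j)
        K = max(1, max((len(k) for k in kids_of), default=1))
        self.child_table = np.full((self.n_segments, K), -1, dtype=int)
        for i, kk in enumerate(kids_of):
            self.child_table[i, :len(kk)] = kk
        # miter-plane normal of each segment's junction with its parent
        nm = self.dirs + self.dirs[np.where(self.parent >= 0, self.parent,
                                            np.arange(self.n_segments))]
        self.miter_normal = nm / np.linalg.norm(nm, axis=1, keepdims=True)
        self.junction_origin = (self.origins
                                + self.lengths[:, None] * self.dirs)
        # carina ridges: each two-child junction carries a rounded rod
        # along the dividing line of the bifurcation (perpendicular to
        # the branching plane).  Its bluntness is scaled to the clearance
        # that the kinked (miter) flow itself generates, so inertialess
        # tracers just clear the ridge while inertial particles, which
        # lag the turn, strike its upstream face -- carinal impaction --
        # and fiber tips can graze it -- interception.
        rp, rd, rr, rh = [], [], [], []
        ridge_of = np.full((self.n_segments, 2), -1, dtype=int)
        for i in range(self.n_segments):
            kids = [int(c) for c in self.child_table[i] if c >= 0]
            if len(kids) != 2:
                continue
            c1, c2 = kids
            u_div = self.dirs[c1] - self.dirs[c2]
            nu = np.linalg.norm(u_div)
            if nu < 1e-9:
                continue
            u_div /= nu
            axis = np.cross(self.dirs[i], u_div)
            na = np.linalg.norm(axis)
            if na < 1e-9:
                continue
            axis /= na
            theta = 0.5 * (self.tilt[c1] + self.tilt[c2])
            gain = self.radii[i] * math.tan(0.5 * theta) * math.sin(theta)
            j = len(rp)
            rp.append(self.junction_origin[i]
                      + max(self.cone_start[c1], self.cone_start[c2])
                      * self.dirs[i])
            rd.append(axis)
            rr.append(self.carina_sharpness * gain)
            rh.append(self.radii[i])
            for s in (i, c1, c2):
                slot = 0 if ridge_of[s, 0] < 0 else 1
                ridge_of[s, slot] = j
        self.ridge_point = np.array(rp) if rp else np.zeros((0, 3))
        self.ridge_dir = np.array(rd) if rd else np.zeros((0, 3))
        self.ridge_radius = np.array(rr) if rr else np.zeros(0)
        self.ridge_halflen = np.array(rh) if rh else np.zeros(0)
        self.ridge_of = ridge_of
        # candidate table for incremental tracking: self, parent, children
        cand = np.full((self.n_segments, 2 + K), -1, dtype=int)
        cand[:, 0] = np.arange(self.n_segments)
        cand[:, 1] = self.parent
        cand[:, 2:] = self.child_table
        self._candidates = np.where(cand < 0, cand[:, :1], cand)

    # -- public views ------------------------------------------------------
    @property
    def segments(self) -> list[TubeSegment]:
        return [
            TubeSegment(self.origins[i].copy(), self.dirs[i].copy(),
                        float(self.lengths[i]), float(self.radii[i]),
                        int(self.generations[i]), self.labels[i])
            for i in range(self.n_segments)
        ]

    @property
    def inlet_origin(self) -> np.ndarray:
        return self.origins[0]

    @property
    def inlet_direction(self) -> np.ndarray:
        return self.dirs[0]

    @property
    def inlet_radius(self) -> float:
        return float(self.radii[0])

    @property
    def inlet_diameter(self) -> float:
        return 2.0 * self.inlet_radius

    @property
    def inlet_area(self) -> float:
        return math.pi * self.inlet_radius ** 2

    def inlet_frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane basis (e1, e2) of the inlet disc."""
        return _plane_basis(self.dirs[0])

    def volume(self) -> float:
        """Total lumen volume, sum of cylinder volumes (m^3)."""
        return float(np.sum(math.pi * self.radii ** 2 * self.lengths))

    # -- distance machinery ------------------------------------------------
    def segment_frames(self, points: np.ndarray, seg_idx: np.ndarray):
        """Axial coordinate z, radial vector and radius of ``points`` in the
        frames of segments ``seg_idx`` (broadcast elementwise)."""
        o = self.origins[seg_idx]
        d = self.dirs[seg_idx]
        w = points - o
        z = np.einsum("...i,...i->...", w, d)
        rvec = w - z[..., None] * d
        r = np.linalg.norm(rvec, axis=-1)
        return z, rvec, r

    def local_radius(self, z, seg_idx):
        """Wall radius at axial coordinate ``z``: the parent radius over
        the junction stub, a linear taper over the transition cone, then
        the segment radius."""
        R_c = self.radii[seg_idx]
        R_b = self.base_radii[seg_idx]
        taper = np.clip(1.0 - (z - self.cone_start[seg_idx])
                        / self.cone_len[seg_idx], 0.0, 1.0)
        return R_c + (R_b - R_c) * taper

    def signed_distance_to(self, points: np.ndarray, seg_idx: np.ndarray):
        """Per-segment signed wall distance (open-ended tapered cylinders).

        Positive inside a segment's lateral extent, non-positive outside;
        exact point-to-axis arithmetic (lateral surfaces only -- inlet and
        outlet discs are open flow boundaries).  At junctions with
        several children the carina septum -- the wedge beyond two or
        more child miter planes -- counts as wall.
        """
        z, _, r = self.segment_frames(points, seg_idx)
        lat = self.local_radius(z, seg_idx) - r
        axial = np.minimum(z, self.lengths[seg_idx]
                           + self.axial_pad[seg_idx] - z)
        s = np.where(axial >= 0.0, lat, np.minimum(lat, axial))

        # carina ridges adjacent to this segment count as wall
        for slot in range(2):
            rj = self.ridge_of[seg_idx, slot]
            if not np.any(rj >= 0):
                continue
            j = np.where(rj >= 0, rj, 0)
            w = points - self.ridge_point[j]
            axdir = self.ridge_dir[j]
            a = np.einsum("...i,...i->...", w, axdir)
            a = np.clip(a, -self.ridge_halflen[j], self.ridge_halflen[j])
            dist = np.linalg.norm(w - a[..., None] * axdir, axis=-1) \
                - self.ridge_radius[j]
            s = np.where(rj >= 0, np.minimum(s, dist), s)
        return s

    def wall_distance(self, point) -> float | np.ndarray:
        """Signed distance to the nearest wall over the whole domain."""
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        all_idx = np.arange(self.n_segments)
        s = self.signed_distance_to(pts[:, None, :], all_idx[None, :])
        best = s.max(axis=1)
        return float(best[0]) if np.asarray(point).ndim == 1 else best

    def nearest_segment(self, point) -> int:
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        all_idx = np.arange(self.n_segments)
        s = self.signed_distance_to(pts[:, None, :], all_idx[None, :])
        return int(np.argmax(s[0]))

    def locate_region(self, point) -> str:
        """Region tag for a point; ``"exited:<label>"`` past an outlet."""
        p = np.asarray(point, dtype=float)
        i = self.nearest_segment(p)
        if self.exit_labels[i] is not None:
            z, _, r = self.segment_frames(p[None, :], np.array([i]))
            if z[0] > self.lengths[i] and r[0] <= self.radii[i]:
                return f"exited:{self.exit_labels[i]}"
        return self.labels[i]

    def probe(self, points: np.ndarray, seg_idx: np.ndarray):
        """Incremental relocation for the tracker.

        Given current segment guesses, re-evaluate membership among each
        guess's neighbourhood (self, parent, children) and flag particles
        that crossed an outlet plane.

        Returns ``(new_seg, signed_dist, exited_mask)``.
        """
        cand = self._candidates[seg_idx]                       # (N, 4)
        s = self.signed_distance_to(points[:, None, :], cand)  # (N, 4)
        pick = np.argmax(s, axis=1)
        rows = np.arange(len(points))
        new_seg = cand[rows, pick]
        best = s[rows, pick]
        # outlet detection on the (possibly updated) segment
        z, _, r = self.segment_frames(points, new_seg)
        has_exit = np.array([self.exit_labels[i] is not None
                             for i in new_seg])
        exited = has_exit & (z > self.lengths[new_seg]) & (r <= self.radii[new_seg])
        return new_seg, best, exited

    def outlet_segments(self) -> list[int]:
        return [i for i in range(self.n_segments)
                if self.exit_labels[i] is not None]


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = _unit(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(helper, d))
    e2 = np.cross(d, e1)
    return e1, e2


class AirwayTree(SegmentedDomain):
    """Symmetric dichotomous bronchial tree (full binary tree of tubes)."""

    name = "tree"

    def __init__(self, *args, root_generation=7, n_levels=9,
                 diameter_ratio=1.0, **kwargs):
        super().__init__(*args, **kwargs)
        self.root_generation = root_generation
        self.terminal_generation = root_generation + n_levels
        self.n_levels = n_levels
        self.diameter_ratio = diameter_ratio

    def generation_diameters(self) -> np.ndarray:
        """Per-generation diameter, root first."""
        out = []
        for g in range(self.root_generation, self.terminal_generation + 1):
            sel = self.generations == g
            out.append(2.0 * float(self.radii[sel][0]))
        return np.asarray(out)


class UpperAirwaySurrogate(SegmentedDomain):
    """Generic conducting-airway analog: tube + constriction + bend + five
    lobar outlet branches.  Explicitly a surrogate -- no anatomical claim."""

    name = "upper"

    def __init__(self, *args, lobar_map=None, **kwargs):
        super().__init__(*args, **kwargs)
        self.lobar_map = dict(lobar_map or {})


class StraightTube(SegmentedDomain):
    """Single straight tube; validation fixture domain."""

    name = "tube"


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_bronchial_tree(root_diameter: float = 2.45e-3,
                         terminal_diameter: float = 0.5e-3,
                         n_bifurcation_levels: int = 9,
                         branching_angle: float = 35.0,
                         length_to_diameter_ratio: float = 3.5,
                         gravity=(0.0, 0.0, 1.0),
                         root_generation: int = 7,
                         branch_angle_shrink: float = 0.85,
                         plane_twist: float = 30.0,
                         validate: bool = True) -> AirwayTree:
    """Build a symmetric dichotomous bronchial tree.

    The tree spans ``n_bifurcation_levels + 1`` airway generations whose
    diameters follow the geometric progression solved so the first equals
    ``root_diameter`` and the last equals ``terminal_diameter`` (default
    2.45 mm down to 0.5 mm, generations 7--16).  Branch length is
    ``length_to_diameter_ratio`` times the local diameter; daughters leave
    the parent axis at the bifurcation half-angle ``branching_angle``
    (degrees), shrunk by ``branch_angle_shrink`` per level so that deep
    subtrees stay inside their own solid-angle sector, with the branching
    plane rotated 90 degrees plus ``plane_twist`` at successive levels to
    fill 3D space without self-intersection.  Gravity defaults to the +z
    axis, which is also the root axis.
    """
    if not (0 < terminal_diameter <= root_diameter):
        raise GeometryError("need 0 < terminal_diameter <= root_diameter")
    if n_bifurcation_levels < 1:
        raise GeometryError("need at least one bifurcation level")
    n = n_bifurcation_levels
    ratio = (terminal_diameter / root_diameter) ** (1.0 / n)
    if not (0 < branching_angle < 90):
        raise GeometryError("degenerate geometry: branching angle must be "
                            "in (0, 90) degrees")
    twist = math.radians(plane_twist)

    origins, dirs, lengths, radii = [], [], [], []
    gens, labels, parent, children, exit_labels, frame_u = [], [], [], [], [], []

    root_dir = _unit(gravity)  # streamwise along gravity in the bronchi model
    e1, _ = _plane_basis(root_dir)

    def add_segment(origin, d, u, level, par):
        idx = len(origins)
        dia = root_diameter * ratio ** level
        origins.append(np.asarray(origin, dtype=float))
        dirs.append(_unit(d))
        lengths.append(length_to_diameter_ratio * dia)
        radii.append(dia / 2.0)
        gens.append(root_generation + level)
        labels.append(f"G{root_generation + level}")
        parent.append(par)
        children.append([-1, -1])
        exit_labels.append(None)
        frame_u.append(np.asarray(u, dtype=float))
        return idx

    root = add_segment((0.0, 0.0, 0.0), root_dir, e1, 0, -1)
    frontier = [root]
    for level in range(1, n + 1):
        theta = math.radians(branching_angle) * branch_angle_shrink ** (level - 1)
        nxt = []
        for par in frontier:
            d = dirs[par]
            u = frame_u[par]
            tip = origins[par] + lengths[par] * d
            d_left = _unit(math.cos(theta) * d + math.sin(theta) * u)
            d_right = _unit(math.cos(theta) * d - math.sin(theta) * u)
            for k, dc in enumerate((d_left, d_right)):
                # next branching plane: normal advanced 90 deg about the
                # parent axis, then twisted about the child axis; the
                # result is exactly orthogonal to the child axis
                u_child = _rotate_about(np.cross(d, u), dc, twist)
                ci = add_segment(tip, dc, u_child, level, par)
                children[par][k] = ci
                nxt.append(ci)
        frontier = nxt

    n_term = 0
    for i in frontier:
        exit_labels[i] = f"{labels[i]}.{n_term}"
        n_term += 1

    tree = AirwayTree(origins, dirs, lengths, radii, gens, labels, parent,
                      children, exit_labels, gravity, frame_u=frame_u,
                      root_generation=root_generation, n_levels=n,
                      diameter_ratio=ratio)
    if validate:
        _check_tree_overlap(tree)
    return tree


def _check_tree_overlap(tree: AirwayTree, n_samples: int = 25) -> None:
    """Reject geometries whose branches intersect in 3D.

    Sibling pairs share the junction point by construction; they are
    admissible only if their distal tips separate by more than the sum of
    their radii.  All other non-adjacent pairs (any generation) must keep
    centreline clearance larger than the sum of their radii, checked on a
    sampled-centreline KD-tree.
    """
    from scipy.spatial import cKDTree

    for par in range(tree.n_segments):
        c0, c1 = tree.children[par]
        if c0 < 0:
            continue
        tip0 = tree.origins[c0] + tree.lengths[c0] * tree.dirs[c0]
        tip1 = tree.origins[c1] + tree.lengths[c1] * tree.dirs[c1]
        if np.linalg.norm(tip0 - tip1) <= tree.radii[c0] + tree.radii[c1]:
            raise GeometryError(
                "degenerate geometry: sibling branches overlap along their "
                "length (increase branching angle or L/D)")

    t = np.linspace(0.0, 1.0, n_samples)
    pts = (tree.origins[:, None, :]
           + t[None, :, None] * tree.lengths[:, None, None]
           * tree.dirs[:, None, :])
    flat = pts.reshape(-1, 3)
    kd = cKDTree(flat)
    pairs = kd.query_pairs(4.0 * tree.radii.max(), output_type="ndarray")
    if len(pairs) == 0:
        return
    si, sj = pairs[:, 0] // n_samples, pairs[:, 1] // n_samples
    par = tree.parent
    adjacent = ((si == sj) | (par[si] == sj) | (par[sj] == si)
                | ((par[si] >= 0) & (par[si] == par[sj])))
    clearance = (np.linalg.norm(flat[pairs[:, 0]] - flat[pairs[:, 1]], axis=1)
                 - tree.radii[si] - tree.radii[sj])
    clearance = np.where(adjacent, np.inf, clearance)
    worst = clearance.min()
    if worst < 0:
        raise GeometryError(
            "degenerate geometry: non-adjacent branches intersect "
            f"(worst clearance {worst:.2e} m)")


def build_upper_surrogate(inlet_diameter: float = 0.02,
                          constriction_ratio: float = 0.5,
                          bend_angle: float = 90.0,
                          lobar_map: dict | None = None,
                          mouth_length: float = 0.065,
                          constriction_length: float = 0.03,
                          pharynx_length: float = 0.015,
                          trachea_length: float = 0.14,
                          trachea_diameter: float = 0.018,
                          outlet_diameter: float = 0.012,
                          outlet_length: float = 0.06,
                          outlet_fan_angle: float = 25.0,
                          elbow_step_deg: float = 15.0,
                          gravity=(0.0, -1.0, 0.0)) -> UpperAirwaySurrogate:
    """Build the generic upper-airway analog.

    Chain: horizontal mouth tube (+x); co-axial contraction into the
    laryngeal-analog constriction (radius = ``constriction_ratio`` x
    inlet radius), which then bends by ``bend_angle`` in total towards
    -y (the bend is discretised into elbow pieces of at most
    ``elbow_step_deg`` each so the flow can follow the turn); co-axial
    diffuser into the vertical trachea; five outlet branches fanning out,
    one per lobar token LU/LL/RU/RM/RL.  Area changes happen in co-axial
    conical transitions and direction changes in small steps, so an
    inertialess tracer traverses the chain without touching a wall.
    Default dimensions give a lumen volume of ~0.1 L, a plausible
    mouth-to-mid-bronchi conducting volume.  ``lobar_map`` maps outlet
    slots 0..4 to lobar tokens and must cover all five lobes exactly
    once.
    """
    if not (0 < constriction_ratio < 1):
        raise GeometryError("constriction_ratio must lie in (0, 1)")
    if lobar_map is None:
        lobar_map = {i: tok for i, tok in enumerate(LOBAR_TOKENS)}
    if sorted(lobar_map.values()) != sorted(LOBAR_TOKENS):
        raise GeometryError(
            f"lobar_map must cover {LOBAR_TOKENS} exactly once, "
            f"got {tuple(lobar_map.values())}")

    g = _unit(gravity)
    down = g.copy()                     # trachea runs along gravity (-y)
    fwd = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(fwd, down)) > 0.9:
        fwd = np.array([0.0, 0.0, 1.0])
    fwd = _unit(fwd - np.dot(fwd, down) * down)

    r_in = inlet_diameter / 2.0
    r_con = constriction_ratio * r_in
    side = np.cross(fwd, down)   # bend plane normal: side x fwd = down

    origins, dirs, lengths, radii = [], [], [], []
    gens, labels, parent, children, exit_labels = [], [], [], [], []

    def add(origin, d, length, radius, label, par, exit_label=None):
        idx = len(origins)
        origins.append(np.asarray(origin, dtype=float))
        dirs.append(_unit(d))
        lengths.append(float(length))
        radii.append(float(radius))
        gens.append(idx)
        labels.append(label)
        parent.append(par)
        children.append([-1, -1])
        if par >= 0 and children[par][0] < 0:
            children[par][0] = idx
        elif par >= 0:
            children[par][1] = idx
        exit_labels.append(exit_label)
        return idx

    cur = add((0.0, 0.0, 0.0), fwd, mouth_length, r_in, "mouth", -1)
    tip = origins[cur] + lengths[cur] * dirs[cur]

    # co-axial contraction + constriction tube (laryngeal jet analog)
    cur = add(tip, fwd, constriction_length, r_con, "constriction", cur)
    tip = origins[cur] + lengths[cur] * dirs[cur]

    # bend in small steps down to `bend_angle`, at constriction radius,
    # with a short straight pharynx piece halfway
    n_steps = max(1, int(math.ceil(bend_angle / elbow_step_deg)))
    step = math.radians(bend_angle) / n_steps
    elbow_len = 0.8 * r_con + r_con * math.tan(step)
    d = dirs[cur]
    half = n_steps // 2
    for k in range(n_steps):
        # rotating about `side` by a positive angle tilts towards `down`
        d = _unit(_rotate_about(d, side, step))
        cur = add(tip, d, elbow_len, r_con, "constriction", cur)
        tip = origins[cur] + lengths[cur] * dirs[cur]
        if k == half - 1 and pharynx_length > 0:
            cur = add(tip, d, pharynx_length, r_con, "constriction", cur)
            tip = origins[cur] + lengths[cur] * dirs[cur]

    # co-axial diffuser into the trachea
    cur = add(tip, dirs[cur], trachea_length, trachea_diameter / 2.0,
              "trachea", cur)
    tra = cur
    tip = origins[cur] + lengths[cur] * dirs[cur]
    d_tra = dirs[tra]

    # five outlet branches: fan around the trachea axis
    phi = math.radians(outlet_fan_angle)
    e1, e2 = _plane_basis(d_tra)
    azimuths = np.linspace(0.0, 2.0 * math.pi, 5, endpoint=False)
    outlet_idx = []
    for slot in range(5):
        tok = lobar_map[slot]
        az = azimuths[slot]
        lateral = math.cos(az) * e1 + math.sin(az) * e2
        d_out = _unit(math.cos(phi) * d_tra + math.sin(phi) * lateral)
        outlet_idx.append(add(tip, d_out, outlet_length,
                              outlet_diameter / 2.0, tok, tra,
                              exit_label=tok))

    return UpperAirwaySurrogate(origins, dirs, lengths, radii, gens, labels,
                                parent, children, exit_labels, gravity,
                                lobar_map=lobar_map)


def build_straight_tube(radius: float, length: float,
                        direction=(1.0, 0.0, 0.0),
                        gravity=(0.0, -1.0, 0.0),
                        region: str = "tube") -> StraightTube:
    """Single tube domain whose far plane is an open outlet."""
    d = _unit(direction)
    return StraightTube([np.zeros(3)], [d], [length], [radius], [0], [region],
                        [-1], [[-1, -1]], [region], gravity)


# ---------------------------------------------------------------------------
# module-level operation wrappers
# ---------------------------------------------------------------------------

def wall_distance(domain: SegmentedDomain, point):
    """Signed distance (m): positive inside the lumen, non-positive outside."""
    return domain.wall_distance(point)


def locate_region(domain: SegmentedDomain, point) -> str:
    """Deterministic region tag; ``"exited:<label>"`` beyond outlet planes."""
    return domain.locate_region(point)


@dataclass
class SeedGrid:
    """Uniform Cartesian lattice clipped to the inlet disc."""

    points: np.ndarray          # (N, 3) positions on the inlet plane
    orientation: np.ndarray     # streamwise unit vector
    pitch: float = field(default=0.0)

    def __len__(self) -> int:
        return len(self.points)


def inlet_seed_grid(domain: SegmentedDomain, n_points: int,
                    margin: float = 1e-3) -> SeedGrid:
    """Uniform Cartesian grid on the inlet disc with ~``n_points`` points.

    The lattice pitch is solved so the clipped point count falls within 10%
    of the request; all points lie strictly inside the lumen (a relative
    ``margin`` of the radius is kept clear of the wall).  Orientation is the
    streamwise inlet direction.
    """
    if n_points < 1:
        raise GeometryError("n_points must be >= 1")
    R = domain.inlet_radius * (1.0 - margin)
    center = domain.inlet_origin + 1e-9 * domain.inlet_direction
    e1, e2 = domain.inlet_frame()
    if n_points == 1:
        return SeedGrid(center[None, :].copy(), domain.inlet_direction.copy(),
                        pitch=0.0)

    def clipped(h):
        k = np.arange(-math.ceil(R / h), math.ceil(R / h) + 1)
        xx, yy = np.meshgrid(k * h, k * h)
        keep = xx ** 2 + yy ** 2 < R ** 2
        return xx[keep], yy[keep]

    h = R * math.sqrt(math.pi / n_points)
    best = None
    for f in np.linspace(0.8, 1.25, 46):
        xx, yy = clipped(h * f)
        err = abs(len(xx) - n_points)
        if best is None or err < best[0]:
            best = (err, h * f, xx, yy)
    _, pitch, xx, yy = best
    pts = (center[None, :] + xx[:, None] * e1[None, :]
           + yy[:, None] * e2[None, :])
    return SeedGrid(pts, domain.inlet_direction.copy(), pitch=pitch)
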