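"""Fiber geometry, aerodynamic descriptors and equations of motion.

Fibers are prolate spheroids described by the volume-equivalent sphere
diameter ``d_p`` and the aspect ratio ``AR = b_p/a_p >= 1`` of major to
minor semi-axis; ``AR = 1`` is a sphere.  Their Stokes-regime aerodynamic
behaviour is summarised by the Stokes-equivalent diameter

    d_Stk = 2 a_p * sqrt( AR * ln(AR + sqrt(AR^2 - 1)) / sqrt(AR^2 - 1) )

whose ``AR -> 1`` limit is ``d_p``, the relaxation time
``t0 = rho_p * d_Stk^2 / (18 mu_air)`` and the Stokes number
``Stk = t0 * u0 / D``.  Elongation at fixed volume always *reduces*
``d_Stk``, ``t0`` and ``Stk``: high-AR fibers act as flow tracers.

Forces: orientation-dependent Stokes drag through the Oberbeck resistance
tensor of a prolate spheroid, Saffman-type shear lift (pluggable), and
gravity.  Rotation follows quasi-steady Jeffery dynamics -- the rotational
relaxation time of micron fibers is far below the flow timescales, so
rotational inertia is neglected.  Brownian motion, electrostatics,
hygroscopic growth and particle-particle interaction are excluded; the
coupling to the flow is one-way.

Translation is advanced by an exponential integrator that is exact for
linear drag with coefficients frozen over the step, so the scheme remains
stable and accurate for relaxation times far below the time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AirProperties",
    "FiberSpec",
    "FiberState",
    "IntegrationError",
    "fiber_axes",
    "stokes_diameter",
    "relaxation_time",
    "stokes_number",
    "oberbeck_resistance",
    "drag_force",
    "jeffery_rotation_rate",
    "saffman_lift",
    "lift_force",
    "advance_state",
    "AIR",
]


class IntegrationError(RuntimeError):
    """Raised when the state integration produces non-finite values."""


@dataclass(frozen=True)
class AirProperties:
    """Ambient air: dynamic viscosity (Pa s), density (kg/m^3), gravity (m/s^2)."""

    viscosity: float = 1.81e-5
    density: float = 1.2
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if min(self.viscosity, self.density, self.gravity) <= 0:
            raise ValueError("air properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


AIR = AirProperties()


def fiber_axes(d_p: float, AR: float) -> tuple[float, float]:
    """Semi-axes (a_p, b_p) of the prolate spheroid with sphere-equivalent
    volume: ``a_p = (d_p/2) * AR**(-1/3)``, ``b_p = AR * a_p``."""
    if d_p <= 0:
        raise ValueError("d_p must be positive")
    if AR < 1:
        raise ValueError("oblate not supported: AR must be >= 1")
    a_p = 0.5 * d_p * AR ** (-1.0 / 3.0)
    return a_p, AR * a_p


def stokes_diameter(a_p: float, AR: float) -> float:
    """Stokes-equivalent diameter of a prolate spheroid.

    Evaluates ``2 a_p sqrt(AR ln(AR + sqrt(AR^2-1)) / sqrt(AR^2-1))``; the
    bracket tends to 1 as ``AR -> 1`` so the sphere limit returns ``2 a_p``.
    """
    if AR < 1:
        raise ValueError("oblate not supported: AR must be >= 1")
    if AR - 1.0 < 1e-12:
        return 2.0 * a_p
    s = math.sqrt(AR * AR - 1.0)
    return 2.0 * a_p * math.sqrt(AR * math.log(AR + s) / s)


def relaxation_time(d_stk: float, rho_p: float, mu_air: float) -> float:
    """Stokes relaxation time ``t0 = rho_p d_Stk^2 / (18 mu_air)`` (s)."""
    if min(d_stk, rho_p, mu_air) <= 0:
        raise ValueError("arguments must be positive")
    return rho_p * d_stk ** 2 / (18.0 * mu_air)


def stokes_number(t0: float, u0: float, D: float) -> float:
    """``Stk = t0 u0 / D`` with u0 the peak inlet centreline velocity."""
    if D <= 0:
        raise ValueError("inlet diameter must be positive")
    return t0 * u0 / D


@dataclass(frozen=True)
class FiberSpec:
    """Geometric and aerodynamic description of one particle group."""

    d_p: float                    # volume-equivalent sphere diameter, m
    AR: float                     # aspect ratio b_p/a_p, >= 1
    density: float = 1000.0       # particle density, kg/m^3
    air: AirProperties = AIR

    a_p: float = field(init=False)
    b_p: float = field(init=False)
    d_stk: float = field(init=False)
    t0: float = field(init=False)
    mass: float = field(init=False)
    k_par: float = field(init=False)   # drag resistance along the fiber axis
    k_perp: float = field(init=False)  # drag resistance across the fiber axis

    def __post_init__(self) -> None:
        a, b = fiber_axes(self.d_p, self.AR)
        object.__setattr__(self, "a_p", a)
        object.__setattr__(self, "b_p", b)
        object.__setattr__(self, "d_stk",
                           stokes_diameter(a, self.AR))
        object.__setattr__(self, "t0",
                           relaxation_time(self.d_stk, self.density,
                                           self.air.viscosity))
        object.__setattr__(self, "mass",
                           self.density * (4.0 / 3.0) * math.pi
                           * (self.d_p / 2.0) ** 3)
        kp, kt = oberbeck_resistance(a, b)
        object.__setattr__(self, "k_par", kp)
        object.__setattr__(self, "k_perp", kt)

    @property
    def jeffery_lambda(self) -> float:
        """Shape factor ``(AR^2-1)/(AR^2+1)`` of the Jeffery equation."""
        return (self.AR ** 2 - 1.0) / (self.AR ** 2 + 1.0)

    def stokes_number(self, u0: float, D: float) -> float:
        return stokes_number(self.t0, u0, D)

    def settling_speed(self) -> float:
        """Stokes terminal speed ``t0 * g`` of the equivalent sphere, m/s."""
        return self.t0 * self.air.gravity


@dataclass
class FiberState:
    """Instantaneous kinematic state of one fiber."""

    position: np.ndarray                  # m
    velocity: np.ndarray                  # m/s
    orientation: np.ndarray               # unit vector along the major axis
    status: str = "airborne"              # airborne | deposited | exited
    group: int = 0
    clock: float = 0.0                    # s

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        p = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(p)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("orientation must be a unit vector")
        self.orientation = p / n


def oberbeck_resistance(a_p: float, b_p: float) -> tuple[float, float]:
    """Translational resistance of a prolate spheroid in Stokes flow.

    Returns ``(K_par, K_perp)`` such that the drag force is
    ``F = mu * [K_par p p^T + K_perp (I - p p^T)] u_rel`` for motion along
    and across the symmetry axis.  With eccentricity
    ``e = sqrt(1 - (a/b)^2)`` and ``L = ln((1+e)/(1-e))``:

        K_par  = 16 pi b e^3 / ((1 + e^2) L - 2 e)
        K_perp = 32 pi b e^3 / ((3 e^2 - 1) L + 2 e)

    Both reduce to the Stokes value ``6 pi a`` as ``e -> 0``.
    """
    if not (0 < a_p <= b_p):
        raise ValueError("need 0 < a_p <= b_p (prolate)")
    e2 = 1.0 - (a_p / b_p) ** 2
    if e2 < 1e-4:
        # near-sphere series; the closed form cancels catastrophically
        k0 = 6.0 * math.pi * b_p
        return k0 * (1.0 - 0.4 * e2), k0 * (1.0 - 0.3 * e2)
    e = math.sqrt(e2)
    L = math.log((1.0 + e) / (1.0 - e))
    k_par = 16.0 * math.pi * b_p * e ** 3 / ((1.0 + e2) * L - 2.0 * e)
    k_perp = 32.0 * math.pi * b_p * e ** 3 / ((3.0 * e2 - 1.0) * L + 2.0 * e)
    return k_par, k_perp


def drag_force(spec: FiberSpec, p_hat, u_rel, air: AirProperties | None = None):
    """Orientation-dependent Stokes drag ``mu K(p) u_rel`` (N)."""
    air = air or spec.air
    p = np.asarray(p_hat, dtype=float)
    u = np.asarray(u_rel, dtype=float)
    upar = np.dot(u, p) * p
    return air.viscosity * (spec.k_par * upar + spec.k_perp * (u - upar))


def jeffery_rotation_rate(spec: FiberSpec, p_hat, grad_u):
    """Quasi-steady Jeffery rate of change of the fiber axis (1/s).

    ``dp/dt = W p + lambda (S p - (p^T S p) p)`` with ``S``/``W`` the
    symmetric/antisymmetric parts of the velocity-gradient tensor
    ``(grad_u)_ij = du_i/dx_j`` and ``lambda = (AR^2-1)/(AR^2+1)``.  The
    result is orthogonal to ``p``.
    """
    p = np.asarray(p_hat, dtype=float)
    G = np.asarray(grad_u, dtype=float)
    S = 0.5 * (G + G.T)
    W = 0.5 * (G - G.T)
    lam = spec.jeffery_lambda
    Sp = S @ p
    return W @ p + lam * (Sp - np.dot(p, Sp) * p)


def saffman_lift(spec: FiberSpec, u_rel, grad_u,
                 air: AirProperties | None = None,
                 coefficient: float = 1.615):
    """Saffman-type shear lift evaluated with ``d_Stk`` as length scale.

    ``F = C mu d_Stk^2 (u_rel x omega) / sqrt(nu |omega|)`` with
    ``omega = curl u``; identically zero in uniform flow or at zero slip.
    In plane shear this reduces to the classical
    ``1.615 mu d^2 |u_rel| sqrt(gamma_dot / nu)`` directed from the
    low- to the high-velocity side for a lagging particle.
    """
    air = air or spec.air
    G = np.asarray(grad_u, dtype=float)
    u = np.asarray(u_rel, dtype=float)
    omega = np.array([G[2, 1] - G[1, 2],
                      G[0, 2] - G[2, 0],
                      G[1, 0] - G[0, 1]])
    wmag = np.linalg.norm(omega)
    if wmag < 1e-300 or not np.any(u):
        return np.zeros(3)
    nu = air.kinematic_viscosity
    return (coefficient * air.viscosity * spec.d_stk ** 2
            / math.sqrt(nu * wmag) * np.cross(u, omega))


def lift_force(spec: FiberSpec, u_rel, grad_u,
               air: AirProperties | None = None, model=saffman_lift):
    """Shear-induced lift force (N); ``model`` is pluggable."""
    if model is None:
        return np.zeros(3)
    return model(spec, u_rel, grad_u, air)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def advance_state(state: FiberState, spec: FiberSpec, flow, air=None,
                  dt: float = 1e-4, gravity_vector=None,
                  lift_model=saffman_lift) -> FiberState:
    """Advance one fiber state by ``dt`` under drag, lift and gravity.

    Translation uses an exponential integrator exact for linear drag with
    coefficients frozen at the step midpoint (one predictor substep);
    orientation follows a midpoint Jeffery update and is renormalised.
    The flow is never modified (one-way coupling).
    """
    if state.status != "airborne":
        raise ValueError("can only advance airborne particles")
    if dt <= 0:
        raise ValueError("dt must be positive")
    air = air or spec.air
    dom = getattr(flow, "domain", None)
    if gravity_vector is None:
        gravity_vector = dom.gravity if dom is not None else np.array([0.0, -1.0, 0.0])
    g = air.gravity * np.asarray(gravity_vector, dtype=float)

    x, v, p = state.position, state.velocity, state.orientation
    t = state.clock
    # predictor: field at the midpoint position and time
    x_mid = x + 0.5 * dt * v
    u_f = np.asarray(flow.velocity(x_mid, t + 0.5 * dt))
    G = np.asarray(flow.gradient(x_mid, t + 0.5 * dt))

    m = spec.mass
    a_par = air.viscosity * spec.k_par / m
    a_perp = air.viscosity * spec.k_perp / m
    c = g + lift_force(spec, u_f - v, G, air, model=lift_model) / m

    def split(w):
        wpar = np.dot(w, p) * p
        return wpar, w - wpar

    x_new = x.copy().astype(float)
    v_new = np.zeros(3)
    for (uc, cc, a) in ((split(u_f)[0], split(c)[0], a_par),
                        (split(u_f)[1], split(c)[1], a_perp)):
        veq = uc + cc / a
        v0 = split(v)[0] if a is a_par else split(v)[1]
        decay = math.exp(-a * dt)
        v_new += veq + (v0 - veq) * decay
        x_new += veq * dt + (v0 - veq) * (1.0 - decay) / a

    # midpoint Jeffery rotation
    k1 = jeffery_rotation_rate(spec, p, G)
    p_half = p + 0.5 * dt * k1
    p_half /= np.linalg.norm(p_half)
    k2 = jeffery_rotation_rate(spec, p_half, G)
    p_new = p + dt * k2
    p_new /= np.linalg.norm(p_new)

    if not (np.all(np.isfinite(x_new)) and np.all(np.isfinite(v_new))
            and np.all(np.isfinite(p_new))):
        raise IntegrationError(
            f"integration blow-up: particle group {state.group} "
            f"at t = {t:.6g} s")
    return FiberState(x_new, v_new, p_new, "airborne", state.group, t + dt)
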