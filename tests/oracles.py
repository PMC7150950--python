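"""Independent analytic oracles used by the test-suite only."""

import math

import numpy as np


def pich_tube_sedimentation(v_s: float, u_mean: float, R: float,
                            L: float) -> float:
    """Gravitational deposition efficiency for fully developed laminar
    flow in a horizontal circular tube (flux-weighted inlet).

    With kappa = (3/8) (v_s / u_mean) (L / R):

        P = (2/pi) [ 2 kappa sqrt(1 - kappa^(2/3))
                     - kappa^(1/3) sqrt(1 - kappa^(2/3))
                     + arcsin(kappa^(1/3)) ],  P = 1 for kappa >= 1.
    """
    kappa = 0.375 * (v_s / u_mean) * (L / R)
    if kappa >= 1.0:
        return 1.0
    k13 = kappa ** (1.0 / 3.0)
    s = math.sqrt(1.0 - k13 * k13)
    return (2.0 / math.pi) * (2.0 * kappa * s - k13 * s + math.asin(k13))


def tube_sedimentation_flux_integral(v_s: float, u_mean: float, R: float,
                                     L: float, n: int = 2000) -> float:
    """Brute-force oracle for the same quantity.

    Uses the trajectory invariant of settling through Poiseuille flow --
    the axial distance travelled before reaching the floor is
    ``(1/v_s) int u(y', z) dy'`` -- and integrates the deposited fraction
    of the inlet flux on a grid.  Entirely independent of the particle
    tracker and of the closed form above.
    """
    y = np.linspace(-1, 1, n)
    z = np.linspace(-1, 1, n)
    Y, Z = np.meshgrid(y, z, indexing="ij")
    inside = Y * Y + Z * Z < 1.0
    u0 = np.maximum(1.0 - Y * Y - Z * Z, 0.0)
    yhit = -np.sqrt(np.maximum(1.0 - Z * Z, 0.0))

    def F(yy):
        return (1.0 - Z * Z) * yy - yy ** 3 / 3.0

    x_hit = (2.0 * u_mean * R / v_s) * (F(Y) - F(yhit))
    dep = x_hit <= L
    return float(np.sum(u0 * dep * inside) / np.sum(u0 * inside))
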