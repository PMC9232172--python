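"""Closed-form layer: hexagonal ground state, elastic moduli, and the
cluster force-balance cubic with its critical densities/contractilities.

Conventions
-----------
* The ground-state cell perimeter L_g is the energy-minimizing positive root
  of  L^3 + 8(12*Gamma - sqrt(3))*L + 48*Lambda = 0, with the regular-hexagon
  relations A = (sqrt(3)/24) L^2 and l = L/6.
* Moduli of the hexagonal ground state:
      K = 9*sqrt(3)*l_g^2 + 8*sqrt(3)*Gamma - 2,     G = 3*(1 - A_g).
  Both equal simple rescalings of second derivatives of the per-cell energy:
  K = 4*A_g * d2e/dA2 under isotropic dilation at fixed hexagonal shape, and
  G = (1/A_g) * d2e/deps2 under area-preserving pure shear.  Numerical
  versions of those derivatives are provided as independent cross-checks.
* The cluster force balance is a cubic in the characteristic length
  u = sqrt(a) (a = cell area = 1/density):
      u^3 - 3*q1*u + 2*q2 = 0,
      q1 = A_N/3 - 2*Gamma*(1 + pi/n),
      q2 = (pi*mu*Lambda - Gamma*L_N*(n - pi)) / (2*n*k),
  with a saddle-node at u = sqrt(q1) when q1 > 0.  ``ring_net_force`` is the
  un-reduced radial force and serves as an independent oracle for the roots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroundState",
    "ForceBalanceModel",
    "ground_state",
    "elastic_moduli",
    "bulk_modulus_numeric",
    "shear_modulus_numeric",
    "hexagon_shape_constant",
    "interfacial_count",
    "force_balance_coefficients",
    "solve_force_balance",
    "critical_point",
    "mu1_from_rho1",
    "scenario2_interface_calibration",
    "rho_mce",
    "rho1_regression",
    "scaling_variable",
    "ring_net_force",
]

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class GroundState:
    L_g: float  # cell perimeter
    A_g: float  # cell area
    l_g: float  # edge length (= L_g / 6)
    K: float  # bulk modulus
    G: float  # shear modulus


def _per_cell_energy_of_area(A: float, lam: float, gamma: float) -> float:
    """Per-cell energy of a regular-hexagon lattice cell of area A.

    Each edge is shared by two cells, so the tension term enters as
    Lambda*L/2 per cell.  L(A) follows from A = (sqrt(3)/24) L^2.
    """
    L = math.sqrt(8.0 * SQRT3 * A)
    return 0.5 * (A - 1.0) ** 2 + 0.5 * lam * L + 0.5 * gamma * L * L


def ground_state(lam: float, gamma: float) -> GroundState:
    """Regular hexagonal-packing ground state for (Lambda, Gamma).

    Raises ValueError outside the regime with a positive energy-minimizing
    root (non-hexagonal ground states are out of scope).
    """
    if lam < 0 or gamma < 0:
        raise ValueError("Lambda and Gamma must be non-negative")
    p = 8.0 * (12.0 * gamma - SQRT3)
    q = 48.0 * lam
    roots = np.roots([1.0, 0.0, p, q])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-10 and r.real > 1e-12]
    if not real:
        raise ValueError(
            f"no hexagonal ground state for (Lambda, Gamma) = ({lam}, {gamma}): "
            "no positive perimeter root"
        )
    L = max(real)  # the larger root is the local energy minimum
    A = (SQRT3 / 24.0) * L * L
    l = L / 6.0
    K = 9.0 * SQRT3 * l * l + 8.0 * SQRT3 * gamma - 2.0
    G = 3.0 * (1.0 - A)
    return GroundState(L_g=L, A_g=A, l_g=l, K=K, G=G)


def elastic_moduli(lam: float, gamma: float) -> tuple[float, float]:
    gs = ground_state(lam, gamma)
    return gs.K, gs.G


def bulk_modulus_numeric(lam: float, gamma: float, h: float = 1e-5) -> float:
    """Oracle: K = 4*A_g * d2e/dA2 by central differences under isotropic dilation."""
    gs = ground_state(lam, gamma)
    e = lambda A: _per_cell_energy_of_area(A, lam, gamma)
    d2 = (e(gs.A_g + h) - 2.0 * e(gs.A_g) + e(gs.A_g - h)) / (h * h)
    return 4.0 * gs.A_g * d2


def shear_modulus_numeric(lam: float, gamma: float, h: float = 1e-4) -> float:
    """Oracle: G = (1/A_g) * d2e/deps2 under the area-preserving pure shear
    (x, y) -> ((1+eps) x, y/(1+eps)) of the ground-state hexagon."""
    gs = ground_state(lam, gamma)
    # regular hexagon: circumradius = edge length l_g
    ang = np.radians(30 + 60 * np.arange(6))
    hexagon = gs.l_g * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    def e(eps: float) -> float:
        pts = hexagon * np.array([1.0 + eps, 1.0 / (1.0 + eps)])
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        per = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum()
        return 0.5 * (area - 1.0) ** 2 + 0.5 * lam * per + 0.5 * gamma * per * per

    d2 = (e(h) - 2.0 * e(0.0) + e(-h)) / (h * h)
    return d2 / gs.A_g


def hexagon_shape_constant() -> float:
    """k with r = k*sqrt(a) for a regular hexagon of area a and edge r."""
    return math.sqrt(2.0 * SQRT3) / 3.0


def interfacial_count(N: float) -> float:
    """Number of interfacial cells n of an N-cell circular cluster of near-regular hexagons."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return math.sqrt(2.0 * SQRT3 * math.pi * N)


def force_balance_coefficients(
    A_N: float, L_N: float, lam: float, gamma: float, mu: float, n: float, k: float
) -> tuple[float, float]:
    q1 = A_N / 3.0 - 2.0 * gamma * (1.0 + math.pi / n)
    q2 = (math.pi * mu * lam - gamma * L_N * (n - math.pi)) / (2.0 * n * k)
    return q1, q2


def solve_force_balance(q1: float, q2: float) -> list[tuple[float, bool]]:
    """Real roots u of u^3 - 3*q1*u + 2*q2 = 0 with stability labels.

    Stability follows the sign of f'(u*) = 3*(q1 - u*^2) for the relaxation
    dynamics du/dt = -(u^3 - 3*q1*u + 2*q2): stable iff u*^2 > q1.
    """
    roots = np.roots([1.0, 0.0, -3.0 * q1, 2.0 * q2])
    out = []
    for r in roots:
        # tolerance ~sqrt(eps): numerical double roots split into +/- i*1e-8
        if abs(r.imag) < 1e-6 * max(1.0, abs(r.real)):
            u = float(r.real)
            out.append((u, u * u > q1))
    out.sort(key=lambda t: t[0])
    return out


def stable_positive_root(q1: float, q2: float) -> float | None:
    cands = [u for u, st in solve_force_balance(q1, q2) if st and u > 1e-12]
    return max(cands) if cands else None


def critical_point(
    A_N: float, L_N: float, lam: float, gamma: float, n: float, k: float
) -> tuple[float, float] | None:
    """Saddle-node density and contractility (rho2, mu2*Lambda); None if q1 <= 0."""
    q1, _ = force_balance_coefficients(A_N, L_N, lam, gamma, 1.0, n, k)
    if q1 <= 0:
        return None
    rho2 = 1.0 / q1
    mu2_lambda = (2.0 * n * k / math.pi) * q1**1.5 + gamma * L_N * (n / math.pi - 1.0)
    return rho2, mu2_lambda


def mu1_from_rho1(
    rho1: float, A_N: float, L_N: float, lam: float, gamma: float, n: float, k: float
) -> float:
    """Contractility mu1*Lambda at which the stable branch reaches density rho1."""
    if rho1 <= 0:
        raise ValueError("rho1 must be positive")
    u1 = rho1**-0.5
    q1, _ = force_balance_coefficients(A_N, L_N, lam, gamma, 1.0, n, k)
    q2_needed = 0.5 * (3.0 * q1 * u1 - u1**3)
    mu1_lambda = (2.0 * n * k * q2_needed + gamma * L_N * (n - math.pi)) / math.pi
    return mu1_lambda


def scenario2_interface_calibration(
    a0: float, lam: float, gamma: float, n: float, k: float
) -> tuple[float, float]:
    """Interfacial normal-cell (A_N, L_N) from the mu = 1 force balance at a = a0.

    Solves A_N + Gamma*L_N*(n-pi)/(n*k*sqrt(a0)) - a0 - 6*Gamma*(n+pi)/n
    - pi*Lambda/(n*k*sqrt(a0)) = 0 jointly with A_N = (sqrt(3)/24) L_N^2;
    this is quadratic in L_N and the positive branch (continuous with the
    ground state as a0 -> A_g) is returned.
    """
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    u0 = math.sqrt(a0)
    c2 = SQRT3 / 24.0
    c1 = gamma * (n - math.pi) / (n * k * u0)
    c0 = -a0 - 6.0 * gamma * (n + math.pi) / n - math.pi * lam / (n * k * u0)
    disc = c1 * c1 - 4.0 * c2 * c0
    if disc < 0:
        raise ValueError("no real interfacial calibration root")
    L_N = (-c1 + math.sqrt(disc)) / (2.0 * c2)
    if L_N <= 0:
        raise ValueError("no positive interfacial calibration root")
    return c2 * L_N * L_N, L_N


def regular_polygon_shape_constant(i: int) -> float:
    """k_i with edge r = k_i*sqrt(a) for a regular i-gon of area a."""
    return math.sqrt(4.0 * math.tan(math.pi / i) / i)


def rho_mce(i: int, lam: float, gamma: float, rho_max: float = 200.0) -> float:
    """Upper limit of surrounding-cell density below which a regular i-gon
    can exist as a mechanically stable cell (single-cell saddle-node).

    Reconstructed as the single-cell analogue of the cluster force balance:
    n = i interfacial contacts, mu = 1, a regular i-gon focal cell (shape
    constant k_i, perimeter i*k_i*u replacing the hexagonal 6*k*u), and
    hexagonal surrounding cells of area 1/rho_s.  Approximate (the exact
    single-cell expressions are not reproduced here):
        q1 = A_s/3 - (i/3)*Gamma*(1 + pi/i)
        q2 = (pi*Lambda - Gamma*L_s*(i - pi)) / (2*i*k_i)
    """
    if i not in (3, 4, 5, 6):
        raise ValueError("polygon class must be 3..6")
    ki = regular_polygon_shape_constant(i)

    def margin(rho_s: float) -> float:
        """Positive while a stable positive root exists."""
        A_s = 1.0 / rho_s
        L_s = math.sqrt(8.0 * SQRT3 * A_s)
        q1 = A_s / 3.0 - (i / 3.0) * gamma * (1.0 + math.pi / i)
        q2 = (math.pi * lam - gamma * L_s * (i - math.pi)) / (2.0 * i * ki)
        if q1 <= 0 and q2 > 0:
            return -1.0
        if q2 <= 0:
            return 1.0
        return q1**1.5 - q2

    from scipy.optimize import brentq

    lo = 1e-3
    if margin(lo) <= 0:
        raise ValueError(f"no stable regular {i}-gon even at vanishing density")
    grid = np.geomspace(lo, rho_max, 400)
    prev = lo
    for rho_s in grid[1:]:
        if margin(float(rho_s)) <= 0:
            return float(brentq(margin, prev, float(rho_s), xtol=1e-12))
        prev = float(rho_s)
    raise ValueError(f"no saddle-node found for i={i} below rho_s={rho_max}")


def rho1_regression(
    rho1_values: np.ndarray, rho_mce_matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """No-intercept least squares of rho1 on (rho_MCE(3), rho_MCE(4), rho_MCE(5)).

    Returns (coefficients c3..c5, fitted values, R^2 about the mean).
    """
    y = np.asarray(rho1_values, dtype=float)
    X = np.asarray(rho_mce_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and rho1 vector sizes differ")
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need more parameter sets than regressors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return coef, fitted, r2


def scaling_variable(lam: float, mu: float, N_theta: float) -> float:
    """Rescaled contractility Lambda*(mu - 1)/sqrt(N_theta) (2D Laplace argument)."""
    if mu < 1:
        raise ValueError("mu must be >= 1")
    if N_theta < 1:
        raise ValueError("N_theta must be >= 1")
    return lam * (mu - 1.0) / math.sqrt(N_theta)


@dataclass
class ForceBalanceModel:
    """Ring-model bundle: cluster size, interface geometry and mechanics."""

    N: float
    lam: float
    gamma: float
    mu: float
    A_N: float
    L_N: float
    n: float | None = None
    k: float | None = None

    def __post_init__(self):
        if self.n is None:
            self.n = interfacial_count(self.N)
        if self.k is None:
            self.k = hexagon_shape_constant()
        if self.n <= math.pi:
            raise ValueError("interfacial count n must exceed pi")

    @property
    def coefficients(self) -> tuple[float, float]:
        return force_balance_coefficients(
            self.A_N, self.L_N, self.lam, self.gamma, self.mu, self.n, self.k
        )

    def equilibria(self) -> list[tuple[float, bool]]:
        return solve_force_balance(*self.coefficients)

    def stable_area(self) -> float | None:
        u = stable_positive_root(*self.coefficients)
        return None if u is None else u * u


def ring_net_force(u: float, model: ForceBalanceModel) -> float:
    """Approximate net radial force on an interfacial cell at length u = sqrt(a).

    Root-equivalent to the cubic: F(u) = -2k * (u^3 - 3*q1*u + 2*q2).
    """
    if u <= 0:
        raise ValueError("u must be positive")
    n, k = model.n, model.k
    r = k * u
    return 2.0 * (
        (model.A_N - u * u) * r
        - math.pi * model.mu * model.lam / n
        - math.pi * model.gamma * (model.L_N + 6.0 * r) / n
        + model.gamma * (model.L_N - 6.0 * r)
    )
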