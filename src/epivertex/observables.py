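"""Densities, outcome classification, side statistics, cell stress, Hill fits.

These work on plain arrays (sampled times / abnormal counts / densities) so
they are independent of the simulation driver; ``experiments.Trajectory``
provides thin conveniences on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .cell_cycle import CellCycleParams, mitotic_target_area
from .mechanics import MechanicalParams, edge_line_tension
from .mesh_core import ABNORMAL, TissueMesh

__all__ = [
    "PhaseDiagram",
    "FAILURE",
    "GROWTH_SUSPENSION",
    "SUCCESS",
    "abnormal_density",
    "inverse_rho_bar",
    "classify_outcome",
    "estimate_rho_star",
    "estimate_rho_doublestar",
    "side_distribution",
    "average_side_distribution",
    "cell_stress_tensor",
    "hill_fit",
]

FAILURE = "failure"
GROWTH_SUSPENSION = "growth_suspension"
SUCCESS = "success"
OUTCOMES = (FAILURE, GROWTH_SUSPENSION, SUCCESS)


def abnormal_density(mesh: TissueMesh) -> float:
    """rho = N / (sum of abnormal cell areas)."""
    ids = mesh.abnormal_ids()
    if not ids:
        raise ValueError("abnormal density undefined: no abnormal cells")
    total = sum(mesh.cell_area(c) for c in ids)
    return len(ids) / total


def inverse_rho_bar(
    times: np.ndarray,
    rho: np.ndarray,
    tau_A: float,
    eliminated: bool = False,
) -> float:
    """1/rho_bar with rho_bar = min over t of the tau_A-window moving average
    of rho(t); defined as 0 for elimination success.

    ``times`` must be (approximately) uniformly sampled and cover at least
    one window.
    """
    if eliminated:
        return 0.0
    times = np.asarray(times, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if times.ndim != 1 or times.shape != rho.shape or times.size < 2:
        raise ValueError("times and rho must be matching 1D arrays")
    dt = np.diff(times)
    if dt.min() <= 0 or dt.max() > 1.5 * dt.mean():
        raise ValueError("samples must be uniform and increasing")
    w = int(round(tau_A / dt.mean()))
    if w < 1:
        w = 1
    if w > times.size:
        raise ValueError("moving-average window longer than the record")
    csum = np.concatenate([[0.0], np.cumsum(rho)])
    avg = (csum[w:] - csum[:-w]) / w
    return 1.0 / float(avg.min())


def classify_outcome(
    times: np.ndarray,
    n_abnormal: np.ndarray,
    tau_A: float,
    gs_threshold: float,
    window_cycles: float = 100.0,
) -> str:
    """failure | growth_suspension | success from an N(t) record.

    Success: N reaches 0.  Failure: N reaches gs_threshold at any time.
    Growth suspension: N stays in (0, gs_threshold) over the whole
    ``window_cycles * tau_A`` window.  A record that is too short to decide
    raises ValueError.
    """
    times = np.asarray(times, dtype=float)
    n = np.asarray(n_abnormal, dtype=float)
    if n.size == 0:
        raise ValueError("empty trajectory")
    if n[-1] == 0:
        return SUCCESS
    if np.any(n >= gs_threshold):
        return FAILURE
    if times[-1] - times[0] + 1e-9 < window_cycles * tau_A:
        raise ValueError(
            f"trajectory covers {times[-1] - times[0]:.3g} < "
            f"{window_cycles * tau_A:.3g} time units and did not terminate"
        )
    return GROWTH_SUSPENSION


def estimate_rho_star(inv_rho_bars_gs: np.ndarray) -> float:
    """rho* with 1/rho* = mean of 1/rho_bar over growth-suspension runs."""
    v = np.asarray(inv_rho_bars_gs, dtype=float)
    if v.size == 0:
        raise ValueError("rho* undefined: no growth-suspension runs")
    return 1.0 / float(v.mean())


def estimate_rho_doublestar(
    mu_grid: np.ndarray,
    outcomes_per_mu: list[list[str]],
    rho_bar_per_mu: list[list[float]],
) -> float:
    """rho** = mean rho_bar at the last mu grid point where >= 50% of runs
    fail, with the jump located as the smallest mu with >= 50% success."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    frac_succ = np.array([np.mean([o == SUCCESS for o in outs]) for outs in outcomes_per_mu])
    frac_fail = np.array([np.mean([o == FAILURE for o in outs]) for outs in outcomes_per_mu])
    jump = np.flatnonzero(frac_succ >= 0.5)
    if jump.size == 0:
        raise ValueError("rho** undefined: no jump to success in the mu grid")
    fail_pts = np.flatnonzero(frac_fail[: jump[0]] >= 0.5)
    if fail_pts.size == 0:
        raise ValueError("rho** undefined: no majority-failure point before the jump")
    vals = [r for r in rho_bar_per_mu[fail_pts[-1]] if np.isfinite(r) and r > 0]
    if not vals:
        raise ValueError("rho** undefined: no finite rho_bar at the pre-jump point")
    return float(np.mean(vals))


def side_distribution(mesh: TissueMesh, cell_ids=None) -> dict[int, float]:
    """Frequencies of polygon classes (number of sides) over a cell subset."""
    ids = list(cell_ids) if cell_ids is not None else mesh.cell_ids()
    if not ids:
        raise ValueError("empty cell subset")
    counts: dict[int, int] = {}
    for c in ids:
        k = len(mesh.loops[c])
        counts[k] = counts.get(k, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}


def average_side_distribution(histograms: list[dict[int, float]]) -> dict[int, float]:
    """Unweighted time average of per-snapshot side histograms."""
    if not histograms:
        raise ValueError("no histograms")
    keys = sorted({k for h in histograms for k in h})
    return {k: float(np.mean([h.get(k, 0.0) for h in histograms])) for k in keys}


def cell_stress_tensor(
    mesh: TissueMesh,
    params: MechanicalParams,
    cell_id: int,
    cycle_params: CellCycleParams | None = None,
    t_now: float = 0.0,
    contractility_active: bool = True,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-cell stress: sigma = -P*I + (1/2A) sum_e T_e (d_e x d_e)/|d_e|.

    P = -(A - A0); the edge tension T_e sums the line tension with the
    perimeter-elastic tensions Gamma*L of the one or two incident cells.
    Returns the tensor and sorted principal stresses (sigma1 >= sigma2).
    """
    if cell_id not in mesh.loops:
        raise KeyError(f"unknown cell {cell_id}")
    cp = cycle_params if cycle_params is not None else CellCycleParams()
    rec = mesh.cells[cell_id]
    area = mesh.cell_area(cell_id)
    a0 = mitotic_target_area(rec, t_now, cp)
    pressure = -(area - a0)
    sigma = -pressure * np.eye(2)
    loop = mesh.loops[cell_id]
    nv = len(loop)
    em = mesh.edge_map()
    for i in range(nv):
        v1, v2 = loop[i], loop[(i + 1) % nv]
        key = (v1, v2) if v1 < v2 else (v2, v1)
        tension = edge_line_tension(mesh, key, params, contractility_active)
        for cid in em[key]:
            tension += params.gamma_for(mesh.cells[cid].cell_type) * mesh.cell_perimeter(cid)
        d = mesh.vertices[v2] - mesh.vertices[v1]
        length = float(np.hypot(d[0], d[1]))
        if length > 0:
            sigma += tension * np.outer(d, d) / length / (2.0 * area)
    evals = np.linalg.eigvalsh(sigma)
    return sigma, (float(evals[1]), float(evals[0]))


def _hill_decreasing(x, K, h):
    return K**h / (x**h + K**h)


def _hill_increasing(x, K, h):
    return x**h / (x**h + K**h)


def hill_fit(x: np.ndarray, frequencies: np.ndarray, increasing: bool = False) -> tuple[float, float]:
    """Least-squares Hill fit; returns (K_h, h) with f(K_h) = 1/2.

    Decreasing form K^h/(x^h + K^h) suits failure curves, increasing form
    x^h/(x^h + K^h) success curves.  Degenerate data (constant frequencies)
    are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(frequencies, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a Hill fit")
    if np.any(x <= 0):
        raise ValueError("x values must be positive")
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate frequencies: no transition to fit")
    form = _hill_increasing if increasing else _hill_decreasing
    # midpoint guess: first crossing of 1/2 (linear interp), else median x
    k0 = float(np.median(x))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    cross = np.flatnonzero(np.diff(np.sign(ys - 0.5)) != 0)
    if cross.size:
        i = cross[0]
        t = (0.5 - ys[i]) / (ys[i + 1] - ys[i])
        k0 = float(xs[i] + t * (xs[i + 1] - xs[i]))
    popt, _ = curve_fit(
        form,
        x,
        y,
        p0=[max(k0, 1e-6), 4.0],
        bounds=([1e-9, 0.05], [1e6, 200.0]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


@dataclass
class PhaseDiagram:
    """Per-mu outcome frequencies from replicated runs, with Hill fits."""

    mu_grid: np.ndarray
    outcomes_per_mu: list[list[str]]
    inv_rho_bar_per_mu: list[list[float]]
    N_theta: int
    lam: float

    def frequencies(self, outcome: str) -> np.ndarray:
        return np.array([np.mean([o == outcome for o in outs]) for outs in self.outcomes_per_mu])

    @property
    def mu_lambda_grid(self) -> np.ndarray:
        return np.asarray(self.mu_grid, dtype=float) * self.lam

    def hill(self, outcome: str, x: np.ndarray | None = None) -> tuple[float, float]:
        if outcome not in (FAILURE, SUCCESS):
            raise ValueError("Hill fits apply to the failure and success curves")
        xx = self.mu_lambda_grid if x is None else np.asarray(x, dtype=float)
        return hill_fit(xx, self.frequencies(outcome), increasing=(outcome == SUCCESS))

    def rho_star(self) -> float:
        vals = [
            v
            for outs, invs in zip(self.outcomes_per_mu, self.inv_rho_bar_per_mu)
            for o, v in zip(outs, invs)
            if o == GROWTH_SUSPENSION
        ]
        return estimate_rho_star(np.asarray(vals))

    def rho_doublestar(self) -> float:
        rho_bars = [[1.0 / v if v > 0 else math.inf for v in invs] for invs in self.inv_rho_bar_per_mu]
        return estimate_rho_doublestar(self.mu_grid, self.outcomes_per_mu, rho_bars)

    def to_rows(self) -> list[dict]:
        rows = []
        for i, mu in enumerate(np.asarray(self.mu_grid, dtype=float)):
            row = {"mu": mu, "mu_lambda": mu * self.lam, "N_theta": self.N_theta}
            for o in OUTCOMES:
                row[f"freq_{o}"] = float(np.mean([x == o for x in self.outcomes_per_mu[i]]))
            row["inv_rho_bar_mean"] = float(np.mean(self.inv_rho_bar_per_mu[i]))
            rows.append(row)
        return rows
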