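"""Per-cell clocks, mitotic target-area growth, and division triggers.

A cell's clock advances linearly; when it reaches a per-cycle threshold
tau*(1 + u), u ~ Uniform(-jitter, +jitter), the cell enters the mitotic
phase, during which its target area grows as 1 + b*(t - entry).  Division
fires when the actual area doubles relative to the area at mitosis entry
(doubling rule) or exceeds it by a fixed increment delta_A (adder rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh_core import ABNORMAL, INTERPHASE, MITOTIC, CellRecord

__all__ = [
    "CellCycleParams",
    "draw_cycle_threshold",
    "initial_clock",
    "advance_cell_cycle",
    "mitotic_target_area",
    "division_trigger",
]

DOUBLING = "doubling"
ADDER = "adder"


@dataclass
class CellCycleParams:
    tau_abnormal: float = 5.0
    tau_normal: float = math.inf
    jitter_fraction: float = 0.2
    growth_rate_b: float = 10.0
    division_rule: str = DOUBLING
    delta_A: float = 0.15
    orientation_rule: str = "random"  # or "long_axis"

    def __post_init__(self):
        if not (self.tau_abnormal > 0):
            raise ValueError("tau_abnormal must be positive (or inf)")
        if not (self.tau_normal > 0):
            raise ValueError("tau_normal must be positive (or inf)")
        if not (0 <= self.jitter_fraction < 1):
            raise ValueError("jitter_fraction must lie in [0, 1)")
        if self.growth_rate_b <= 0:
            raise ValueError("growth_rate_b must be positive")
        if self.delta_A <= 0:
            raise ValueError("delta_A must be positive")
        if self.division_rule not in (DOUBLING, ADDER):
            raise ValueError(f"unknown division_rule {self.division_rule!r}")
        if self.orientation_rule not in ("random", "long_axis"):
            raise ValueError(f"unknown orientation_rule {self.orientation_rule!r}")

    def tau_for(self, cell_type: str) -> float:
        return self.tau_abnormal if cell_type == ABNORMAL else self.tau_normal

    @property
    def relative_growth_rate(self) -> float:
        """r = tau_N / tau_A."""
        return self.tau_normal / self.tau_abnormal


def draw_cycle_threshold(cell_type: str, params: CellCycleParams, rng: np.random.Generator) -> float:
    """Per-cycle clock threshold tau*(1 + u), u ~ U(-jitter, +jitter); redrawn at each birth."""
    tau = params.tau_for(cell_type)
    if math.isinf(tau):
        return math.inf
    u = rng.uniform(-params.jitter_fraction, params.jitter_fraction)
    return tau * (1.0 + u)


def initial_clock(cell_type: str, params: CellCycleParams, rng: np.random.Generator) -> float:
    """Initial clock phase at t = 0, uniform on [0, tau) to desynchronize the first wave."""
    tau = params.tau_for(cell_type)
    if math.isinf(tau):
        return 0.0
    return float(rng.uniform(0.0, tau))


def advance_cell_cycle(
    cycle_states: dict[int, CellRecord],
    dt: float,
    params: CellCycleParams,
    rng: np.random.Generator,
    t_now: float = 0.0,
) -> list[int]:
    """Advance all clocks by dt; returns ids of cells that entered mitosis.

    A cell whose threshold was never drawn (e.g. fresh fixture) gets one
    drawn here lazily so fixtures need no extra setup.
    """
    entered: list[int] = []
    for cid, rec in cycle_states.items():
        rec.clock += dt
        if rec.phase != INTERPHASE:
            continue
        if math.isinf(rec.cycle_threshold) and not math.isinf(params.tau_for(rec.cell_type)):
            rec.cycle_threshold = draw_cycle_threshold(rec.cell_type, params, rng)
        if rec.clock >= rec.cycle_threshold:
            rec.phase = MITOTIC
            rec.mitosis_entry_time = t_now + dt
            entered.append(cid)
    return entered


def mitotic_target_area(state: CellRecord, t_now: float, params: CellCycleParams) -> float:
    """Target area 1 + b*(t - mitosis entry) during mitosis; 1 in interphase."""
    if state.phase != MITOTIC or math.isnan(state.mitosis_entry_time):
        return 1.0
    return 1.0 + params.growth_rate_b * max(0.0, t_now - state.mitosis_entry_time)


def division_trigger(state: CellRecord, current_area: float, params: CellCycleParams) -> bool:
    """True when a mitotic cell's actual area reaches its division criterion."""
    if state.phase != MITOTIC or math.isnan(state.area_at_mitosis_entry):
        return False
    if params.division_rule == DOUBLING:
        return current_area >= 2.0 * state.area_at_mitosis_entry
    return current_area >= state.area_at_mitosis_entry + params.delta_A
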