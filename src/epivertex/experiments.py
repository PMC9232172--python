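"""Simulation drivers: scenario 1/2 elimination runs, fixed-wall
proliferation, contractility sweeps and relative-growth experiments.

The driver integrates the vertex dynamics in compiled-array chunks
(``_kernel.run_chunk``), returning to Python only when a topological event
candidate appears; surgery is then applied through ``topology_events`` and
the arrays recompiled.  All randomness flows from a single seed, split into
independent streams (cell-cycle jitter, division orientation, scenario-2
cell choice) so that toggling one feature does not shift another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .cell_cycle import ADDER, CellCycleParams, draw_cycle_threshold, initial_clock
from .mechanics import MechanicalParams, compile_mesh
from .mesh_core import (
    ABNORMAL,
    INTERPHASE,
    MITOTIC,
    NORMAL,
    TissueMesh,
    build_hexagonal_tissue,
)
from .observables import (
    FAILURE,
    GROWTH_SUSPENSION,
    SUCCESS,
    PhaseDiagram,
    classify_outcome,
    inverse_rho_bar,
)
from .theory import ground_state
from .topology_events import EventLog, resolve_events

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "FixedWallResult",
    "Simulation",
    "run_scenario1",
    "run_scenario2",
    "run_fixed_wall",
    "sweep_contractility",
    "run_relative_growth_experiment",
]

# cooldown (time units) before re-examining a skipped event candidate
SKIP_COOLDOWN = 0.02


@dataclass
class SimulationConfig:
    mechanics: MechanicalParams = field(default_factory=MechanicalParams)
    cycle: CellCycleParams = field(default_factory=CellCycleParams)
    scenario: object = 1  # 1 | 2 | "fixed_wall"
    N_theta: int = 10
    tissue_size: int = 200
    wall_radius: float | None = None
    t_end_cycles: float = 100.0  # duration in units of tau_A after onset
    relax_time: float = 2.0
    sample_dt: float | None = None  # default tau_A / 50
    failure_threshold: float | None = None  # default 2 * N_theta (= gs threshold)
    seed: int = 0

    def __post_init__(self):
        if self.N_theta < 1:
            raise ValueError("N_theta must be >= 1")
        if self.t_end_cycles <= 0:
            raise ValueError("t_end_cycles must be positive")
        if self.scenario not in (1, 2, "fixed_wall"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == 1 and self.N_theta > self.tissue_size:
            raise ValueError("N_theta exceeds tissue size")

    @property
    def gs_threshold(self) -> float:
        return (
            self.failure_threshold if self.failure_threshold is not None else 2.0 * self.N_theta
        )

    @property
    def t_end(self) -> float:
        return self.t_end_cycles * self.cycle.tau_abnormal


@dataclass
class Trajectory:
    times: np.ndarray
    n_abnormal: np.ndarray
    area_abnormal: np.ndarray  # summed area of abnormal cells
    area_total: np.ndarray
    onset_time: float
    a0: float  # mean abnormal area just before contractility onset
    eliminated: bool
    reached_cap: bool
    event_log: EventLog
    final_mesh: TissueMesh
    config: SimulationConfig
    seed: int

    @property
    def rho(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.n_abnormal > 0, self.n_abnormal / self.area_abnormal, np.nan)

    @property
    def rho_total(self) -> np.ndarray:
        """All-cell density N_total-independent: here n over total area is not
        tracked per type; use area_total with the abnormal count only where
        every cell is abnormal (fixed-wall runs)."""
        return self.n_abnormal / self.area_total

    def post_onset(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.times >= self.onset_time - 1e-9
        return self.times[m], self.rho[m]

    def inverse_rho_bar(self) -> float:
        if self.eliminated:
            return 0.0
        t, r = self.post_onset()
        ok = np.isfinite(r)
        return inverse_rho_bar(t[ok], r[ok], self.config.cycle.tau_abnormal, eliminated=False)

    def classify(self) -> str:
        m = self.times >= self.onset_time - 1e-9
        return classify_outcome(
            self.times[m],
            self.n_abnormal[m],
            self.config.cycle.tau_abnormal,
            self.config.gs_threshold,
            window_cycles=self.config.t_end_cycles,
        )


@dataclass
class FixedWallResult:
    rho1: float
    rho1_std: float
    trajectory: Trajectory
    warning: str | None = None


class Simulation:
    """Stateful driver around one TissueMesh."""

    def __init__(
        self,
        mesh: TissueMesh,
        mech: MechanicalParams,
        cycle: CellCycleParams,
        seed: int = 0,
        contractility_active: bool = True,
        t0: float = 0.0,
        wall_radius: float | None = None,
    ):
        self.mesh = mesh
        self.mech = mech
        self.cycle = cycle
        self.wall_radius = wall_radius
        ss = np.random.SeedSequence(seed)
        s_cycle, s_orient, s_misc = ss.spawn(3)
        self.rng_cycle = np.random.default_rng(s_cycle)
        self.rng_orient = np.random.default_rng(s_orient)
        self.rng_misc = np.random.default_rng(s_misc)
        self.t = t0
        self.contractility_active = contractility_active
        gs = ground_state(mech.lambda_normal, mech.gamma_normal)
        self.theta_t1 = mech.theta_t1_rel * gs.l_g
        self.theta_t2 = mech.theta_t2_rel * gs.A_g
        self.ground = gs
        self.log = EventLog()
        self._edge_cooldown: dict[tuple[int, int], float] = {}
        self._cell_cooldown: dict[int, float] = {}

    # -------------------------------------------------------------- setup helpers

    def init_cycle_states(self, initial_phase_spread: bool = True) -> None:
        for cid, rec in self.mesh.cells.items():
            rec.cycle_threshold = draw_cycle_threshold(rec.cell_type, self.cycle, self.rng_cycle)
            rec.clock = (
                initial_clock(rec.cell_type, self.cycle, self.rng_cycle)
                if initial_phase_spread
                else 0.0
            )
            rec.phase = INTERPHASE
            rec.mitosis_entry_time = math.nan
            rec.area_at_mitosis_entry = math.nan

    def relax(self, duration: float, sample_dt: float = 0.0) -> None:
        """Integrate with cell cycling frozen (pure mechanical relaxation)."""
        saved = [(rec.cycle_threshold, rec.clock) for rec in self.mesh.cells.values()]
        for rec in self.mesh.cells.values():
            rec.cycle_threshold = math.inf
        self.run_until(self.t + duration, sample_dt=0.0)
        for (thr, clock), rec in zip(saved, self.mesh.cells.values()):
            rec.cycle_threshold = thr
            rec.clock = clock

    # -------------------------------------------------------------- main loop

    def _compile(self):
        cm = compile_mesh(self.mesh, self.mech, self.contractility_active)
        C = len(cm.cell_order)
        entry_time = np.empty(C)
        area_entry = np.empty(C)
        div_not_before = np.full(C, -np.inf)
        t2_not_before = np.full(C, -np.inf)
        for i, cid in enumerate(cm.cell_order):
            rec = self.mesh.cells[cid]
            if rec.phase == MITOTIC:
                entry_time[i] = rec.mitosis_entry_time
                area_entry[i] = rec.area_at_mitosis_entry
            else:
                entry_time[i] = (
                    self.t + (rec.cycle_threshold - rec.clock)
                    if math.isfinite(rec.cycle_threshold)
                    else np.inf
                )
                area_entry[i] = np.nan
            cd = self._cell_cooldown.get(cid)
            if cd is not None:
                div_not_before[i] = cd
                t2_not_before[i] = cd
            # wall-touching cells can never be T2-removed; don't stop for them
            if any(self.mesh.fixed[v] for v in self.mesh.loops[cid]):
                t2_not_before[i] = np.inf
        edge_ok = np.full(len(cm.edge_keys), -np.inf)
        for k, key in enumerate(cm.edge_keys):
            cd = self._edge_cooldown.get(key)
            if cd is not None:
                edge_ok[k] = cd
            if self.mesh.fixed[key[0]] or self.mesh.fixed[key[1]]:
                edge_ok[k] = np.inf  # T1 never applies on wall vertices
        return cm, entry_time, area_entry, div_not_before, t2_not_before, edge_ok

    def _sync_records(self, cm, entry_time, area_entry, elapsed: float) -> None:
        cm.sync_positions(self.mesh)
        for i, cid in enumerate(cm.cell_order):
            rec = self.mesh.cells.get(cid)
            if rec is None:
                continue
            rec.clock += elapsed
            if rec.phase == INTERPHASE and not math.isnan(area_entry[i]):
                rec.phase = MITOTIC
                rec.mitosis_entry_time = float(entry_time[i])
                rec.area_at_mitosis_entry = float(area_entry[i])

    def run_until(
        self,
        t_end: float,
        sample_dt: float = 0.0,
        stop_when_no_abnormal: bool = False,
        abnormal_cap: float = math.inf,
        check_every: int = 2,
    ):
        """Integrate to t_end, resolving topological events as they arise.

        Returns (times, n_abnormal, area_abnormal, area_total) sample arrays
        (empty when sample_dt == 0).
        """
        dt = self.mech.dt
        cap_samples = 16 + (int((t_end - self.t) / sample_dt) + 4 if sample_dt > 0 else 0)
        samp_t = np.empty(cap_samples)
        samp_n = np.empty(cap_samples, dtype=np.int64)
        samp_aa = np.empty(cap_samples)
        samp_at = np.empty(cap_samples)
        n_samp = 0
        next_sample_t = self.t if sample_dt > 0 else math.inf
        dirty = True
        cm = entry_time = area_entry = div_nb = t2_nb = edge_ok = None
        guard = 0
        while self.t < t_end - 1e-12:
            if dirty:
                cm, entry_time, area_entry, div_nb, t2_nb, edge_ok = self._compile()
                dirty = False
            max_steps = int(math.ceil((t_end - self.t) / dt - 1e-9))
            steps, code, idx, t_new, n_samp, next_sample_t = _kernel.run_chunk(
                cm.pos,
                cm.mobile,
                cm.cstart,
                cm.cverts,
                cm.gamma_c,
                cm.abn,
                entry_time,
                area_entry,
                0 if self.cycle.division_rule != ADDER else 1,
                self.cycle.delta_A,
                self.cycle.growth_rate_b,
                div_nb,
                t2_nb,
                cm.edge_v,
                cm.edge_lam,
                cm.edge_interior,
                edge_ok,
                self.theta_t1,
                self.theta_t2,
                self.wall_radius if self.wall_radius is not None else 0.0,
                self.t,
                dt,
                max_steps,
                check_every,
                sample_dt if sample_dt > 0 else 0.0,
                next_sample_t,
                samp_t,
                samp_n,
                samp_aa,
                samp_at,
                n_samp,
            )
            elapsed = t_new - self.t
            self._sync_records(cm, entry_time, area_entry, elapsed)
            self.t = t_new
            if code == _kernel.DONE:
                break
            # event candidate: resolve everything visible, with skip cooldowns
            skip_edges: set = set()
            skip_cells: set = set()
            before = len(self.log)
            resolve_events(
                self.mesh,
                self.theta_t1,
                self.theta_t2,
                self.cycle,
                self.rng_orient,
                t_now=self.t,
                log=self.log,
                skip_edges=skip_edges,
                skip_cells=skip_cells,
            )
            for key in skip_edges:
                self._edge_cooldown[key] = self.t + SKIP_COOLDOWN
            for cid in skip_cells:
                self._cell_cooldown[cid] = self.t + SKIP_COOLDOWN
            if len(self.log) == len(skip_edges) + len(skip_cells) + before and steps == 0:
                guard += 1
                if guard > 1000:
                    raise RuntimeError("event resolution stalled (livelock)")
            else:
                guard = 0
            dirty = True
            n_abn = len(self.mesh.abnormal_ids())
            if stop_when_no_abnormal and n_abn == 0:
                break
            if n_abn >= abnormal_cap:
                break
        if cm is not None and not dirty:
            cm.sync_positions(self.mesh)
        return (
            samp_t[:n_samp].copy(),
            samp_n[:n_samp].copy(),
            samp_aa[:n_samp].copy(),
            samp_at[:n_samp].copy(),
        )


# ------------------------------------------------------------------ experiment drivers


def _prepare_tissue(config: SimulationConfig, boundary: str) -> TissueMesh:
    gs = ground_state(config.mechanics.lambda_normal, config.mechanics.gamma_normal)
    size = config.tissue_size
    if config.wall_radius is not None and config.scenario == "fixed_wall":
        size = max(1, int(round(math.pi * config.wall_radius**2 / gs.A_g)))
    return build_hexagonal_tissue(size, gs.l_g, boundary)


def _mark_central_cluster(mesh: TissueMesh, n: int) -> list[int]:
    """Relabel the n cells nearest the tissue centroid as abnormal."""
    center = np.mean(
        [mesh.cell_centroid(c) for c in mesh.cell_ids()], axis=0
    )
    by_dist = sorted(
        mesh.cell_ids(), key=lambda c: float(np.linalg.norm(mesh.cell_centroid(c) - center))
    )
    chosen = by_dist[:n]
    for c in chosen:
        mesh.cells[c].cell_type = ABNORMAL
    return chosen


def _sampled_trajectory(config, sim, parts, onset_time, a0, eliminated, reached_cap):
    times = np.concatenate([p[0] for p in parts]) if parts else np.empty(0)
    n_abn = np.concatenate([p[1] for p in parts]) if parts else np.empty(0, dtype=int)
    a_abn = np.concatenate([p[2] for p in parts]) if parts else np.empty(0)
    a_tot = np.concatenate([p[3] for p in parts]) if parts else np.empty(0)
    # append a terminal sample reflecting the final state
    n_now = len(sim.mesh.abnormal_ids())
    a_now = sum(sim.mesh.cell_area(c) for c in sim.mesh.abnormal_ids())
    tot_now = sum(sim.mesh.cell_area(c) for c in sim.mesh.cell_ids())
    times = np.append(times, sim.t)
    n_abn = np.append(n_abn, n_now)
    a_abn = np.append(a_abn, a_now)
    a_tot = np.append(a_tot, tot_now)
    return Trajectory(
        times=times,
        n_abnormal=n_abn.astype(int),
        area_abnormal=a_abn,
        area_total=a_tot,
        onset_time=onset_time,
        a0=a0,
        eliminated=eliminated,
        reached_cap=reached_cap,
        event_log=sim.log,
        final_mesh=sim.mesh,
        config=config,
        seed=config.seed,
    )


def run_scenario1(config: SimulationConfig) -> Trajectory:
    """Abnormal cluster of N_theta central cells; contractility on from t = 0."""
    if config.scenario != 1:
        raise ValueError("config.scenario must be 1")
    mesh = _prepare_tissue(config, "free")
    sim = Simulation(mesh, config.mechanics, config.cycle, seed=config.seed)
    sim.init_cycle_states()
    sim.relax(config.relax_time)
    _mark_central_cluster(mesh, config.N_theta)
    # re-draw cycle state for the abnormal cells (they now cycle with tau_A)
    for c in mesh.abnormal_ids():
        rec = mesh.cells[c]
        rec.cycle_threshold = draw_cycle_threshold(ABNORMAL, config.cycle, sim.rng_cycle)
        rec.clock = initial_clock(ABNORMAL, config.cycle, sim.rng_cycle)
    onset = sim.t
    a0 = float(np.mean([mesh.cell_area(c) for c in mesh.abnormal_ids()]))
    sample_dt = config.sample_dt or config.cycle.tau_abnormal / 50.0
    parts = [
        sim.run_until(
            onset + config.t_end,
            sample_dt=sample_dt,
            stop_when_no_abnormal=True,
            abnormal_cap=config.gs_threshold,
        )
    ]
    n_abn = len(mesh.abnormal_ids())
    return _sampled_trajectory(
        config, sim, parts, onset, a0, eliminated=(n_abn == 0), reached_cap=n_abn >= config.gs_threshold
    )


def run_scenario2(config: SimulationConfig) -> Trajectory:
    """One random interior cell turns abnormal and grows; contractility starts
    once the clone reaches N_theta cells."""
    if config.scenario != 2:
        raise ValueError("config.scenario must be 2")
    mesh = _prepare_tissue(config, "free")
    sim = Simulation(mesh, config.mechanics, config.cycle, seed=config.seed, contractility_active=False)
    sim.init_cycle_states()
    sim.relax(config.relax_time)
    boundary_cells = {
        cid
        for cid in mesh.cell_ids()
        for v in mesh.loops[cid]
        if v in mesh.boundary_vertices()
    }
    interior = [c for c in mesh.cell_ids() if c not in boundary_cells]
    if not interior:
        raise ValueError("tissue too small: no interior cell for the abnormal seed")
    # pick among the innermost third so the clone can reach N_theta before the boundary
    center = np.mean([mesh.cell_centroid(c) for c in mesh.cell_ids()], axis=0)
    interior.sort(key=lambda c: float(np.linalg.norm(mesh.cell_centroid(c) - center)))
    pool = interior[: max(1, len(interior) // 3)]
    seed_cell = int(sim.rng_misc.choice(pool))
    rec = mesh.cells[seed_cell]
    rec.cell_type = ABNORMAL
    rec.cycle_threshold = draw_cycle_threshold(ABNORMAL, config.cycle, sim.rng_cycle)
    rec.clock = initial_clock(ABNORMAL, config.cycle, sim.rng_cycle)
    sample_dt = config.sample_dt or config.cycle.tau_abnormal / 50.0
    parts = []
    # growth stage: run until the clone reaches N_theta
    growth_cap_time = sim.t + 40.0 * config.cycle.tau_abnormal
    while len(mesh.abnormal_ids()) < config.N_theta:
        if sim.t >= growth_cap_time:
            raise RuntimeError("scenario 2: clone failed to reach N_theta in time")
        parts.append(
            sim.run_until(
                min(sim.t + config.cycle.tau_abnormal / 4.0, growth_cap_time),
                sample_dt=sample_dt,
                abnormal_cap=config.N_theta,
            )
        )
        boundary_ids = mesh.boundary_vertices()
        touching = any(
            v in boundary_ids for c in mesh.abnormal_ids() for v in mesh.loops[c]
        )
        if touching:
            raise RuntimeError("scenario 2: abnormal clone reached the tissue boundary")
    onset = sim.t
    a0 = float(np.mean([mesh.cell_area(c) for c in mesh.abnormal_ids()]))
    sim.contractility_active = True
    parts.append(
        sim.run_until(
            onset + config.t_end,
            sample_dt=sample_dt,
            stop_when_no_abnormal=True,
            abnormal_cap=config.gs_threshold,
        )
    )
    n_abn = len(mesh.abnormal_ids())
    return _sampled_trajectory(
        config, sim, parts, onset, a0, eliminated=(n_abn == 0), reached_cap=n_abn >= config.gs_threshold
    )


def run_fixed_wall(config: SimulationConfig) -> FixedWallResult:
    """Proliferation in a rigid circular container; returns the plateau
    density rho1.

    The container is a hard circular wall at the initial tissue radius:
    vertices are radially clamped to it but slide freely along it.  (A
    literal ring of immobilized vertices leaves permanently un-removable
    crushed cells at high density; the container realizes the same
    restricted-space setup without that artifact.)  All cells carry the
    abnormal label (so the proliferation machinery and the density samplers
    apply to them); with a single cell type present no interfacial
    contractility exists.  rho1 is the time average of N / (total area)
    over the second half of the run.
    """
    if config.scenario != "fixed_wall":
        raise ValueError("config.scenario must be 'fixed_wall'")
    mesh = _prepare_tissue(config, "free")
    # wall = the outermost cell ring, anchored at its outer rim and excluded
    # from cycling and from the density measurement; interior cells (labelled
    # abnormal so the proliferation machinery and samplers address them)
    # divide with tau_A
    boundary_vs = mesh.boundary_vertices()
    wall_cells = {c for c in mesh.cell_ids() if any(v in boundary_vs for v in mesh.loops[c])}
    for v in boundary_vs:
        mesh.fixed[v] = True
    for cid, rec in mesh.cells.items():
        rec.cell_type = NORMAL if cid in wall_cells else ABNORMAL
    if len(wall_cells) == len(mesh.loops):
        raise ValueError("tissue too small: no interior cells inside the wall ring")
    sim = Simulation(mesh, config.mechanics, config.cycle, seed=config.seed)
    sim.init_cycle_states()
    for cid in wall_cells:  # wall cells never cycle regardless of tau_normal
        mesh.cells[cid].cycle_threshold = math.inf
    sample_dt = config.sample_dt or config.cycle.tau_abnormal / 50.0
    parts = [sim.run_until(config.t_end, sample_dt=sample_dt)]
    traj = _sampled_trajectory(config, sim, parts, 0.0, math.nan, False, False)
    half = traj.times >= 0.5 * traj.times[-1]
    dens = traj.rho[half]  # interior-cell density N/area
    rho1 = float(dens.mean())
    warning = None
    # plateau check: compare means of 3rd and 4th quarters
    q3 = (traj.times >= 0.5 * traj.times[-1]) & (traj.times < 0.75 * traj.times[-1])
    q4 = traj.times >= 0.75 * traj.times[-1]
    if q3.sum() > 2 and q4.sum() > 2:
        m3 = float(traj.rho[q3].mean())
        m4 = float(traj.rho[q4].mean())
        if abs(m4 - m3) > 0.1 * rho1:
            warning = f"density still trending ({m3:.3g} -> {m4:.3g}); run longer"
    return FixedWallResult(rho1=rho1, rho1_std=float(dens.std()), trajectory=traj, warning=warning)


def _run_one(config: SimulationConfig) -> Trajectory:
    return run_scenario1(config) if config.scenario == 1 else run_scenario2(config)


def sweep_contractility(
    base_config: SimulationConfig, mu_grid, n_runs: int = 5
) -> PhaseDiagram:
    """Replicated runs over a mu grid, classified into the three outcomes."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    outcomes: list[list[str]] = []
    inv_rho: list[list[float]] = []
    for mu in mu_grid:
        outs, invs = [], []
        for i in range(n_runs):
            cfg = replace(
                base_config,
                mechanics=replace(base_config.mechanics, mu=float(mu)),
                seed=int(np.random.SeedSequence([base_config.seed, int(round(mu * 1e6)), i]).generate_state(1)[0] % (2**31)),
            )
            traj = _run_one(cfg)
            outs.append(traj.classify())
            invs.append(traj.inverse_rho_bar() if outs[-1] != SUCCESS else 0.0)
        outcomes.append(outs)
        inv_rho.append(invs)
    return PhaseDiagram(
        mu_grid=np.asarray(mu_grid, dtype=float),
        outcomes_per_mu=outcomes,
        inv_rho_bar_per_mu=inv_rho,
        N_theta=base_config.N_theta,
        lam=base_config.mechanics.lambda_normal,
    )


def run_relative_growth_experiment(
    base_config: SimulationConfig, r_values, mu_grid, n_runs: int = 5
) -> dict[float, PhaseDiagram]:
    """Sweeps at tau_N = r * tau_A for each relative growth rate r."""
    out = {}
    for r in r_values:
        tau_n = math.inf if math.isinf(r) else r * base_config.cycle.tau_abnormal
        cfg = replace(base_config, cycle=replace(base_config.cycle, tau_normal=tau_n))
        out[float(r)] = sweep_contractility(cfg, mu_grid, n_runs)
    return out
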