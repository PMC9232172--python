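"""Tissue energy, vertex forces and explicit Euler integration.

Energy per tissue:  U = sum_cells (A - A0)^2/2  +  sum_edges Lambda_e * l_e
                      + sum_cells (Gamma/2) * L^2
with A0 = 1 in interphase and 1 + b*(t - entry) during mitosis.  Edges
between normal and abnormal cells carry a mu-fold line tension when the
interfacial contractility is active.  Forces are the exact analytic
gradients; fixed-wall vertices are immobile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .cell_cycle import CellCycleParams, mitotic_target_area
from .mesh_core import ABNORMAL, TissueMesh

__all__ = [
    "MechanicalParams",
    "edge_line_tension",
    "total_energy",
    "vertex_forces",
    "euler_step",
    "CompiledMesh",
    "compile_mesh",
]


@dataclass
class MechanicalParams:
    lambda_normal: float = 0.12
    lambda_abnormal: float = 0.12
    gamma_normal: float = 0.04
    gamma_abnormal: float = 0.04
    mu: float = 1.0
    theta_t1_rel: float = 0.01  # T1 threshold / mean ground-state edge length
    theta_t2_rel: float = 0.01  # T2 threshold / mean ground-state cell area
    dt: float = 1e-4

    def __post_init__(self):
        if self.lambda_normal < 0 or self.lambda_abnormal < 0:
            raise ValueError("line-tension coefficients must be >= 0")
        if self.gamma_normal < 0 or self.gamma_abnormal < 0:
            raise ValueError("perimeter-elasticity coefficients must be >= 0")
        if self.mu < 1:
            raise ValueError("mu must be >= 1")
        if not (0 < self.theta_t1_rel < 1 and 0 < self.theta_t2_rel < 1):
            raise ValueError("T1/T2 relative thresholds must lie in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def lambda_for(self, cell_type: str) -> float:
        return self.lambda_abnormal if cell_type == ABNORMAL else self.lambda_normal

    def gamma_for(self, cell_type: str) -> float:
        return self.gamma_abnormal if cell_type == ABNORMAL else self.gamma_normal


def edge_line_tension(
    mesh: TissueMesh,
    edge: tuple[int, int],
    params: MechanicalParams,
    contractility_active: bool = True,
) -> float:
    """Line-tension coefficient of one physical edge.

    Normal-abnormal edges get mu times the base coefficient while the
    contractility is active; when the two cell types carry different Lambda
    the base is their arithmetic mean (symmetric choice; the mixed-property
    experiments keep Lambda equal across types).  Boundary edges use the
    single incident cell's Lambda.
    """
    a, b = edge
    key = (a, b) if a < b else (b, a)
    cids = mesh.edge_map().get(key)
    if not cids:
        raise KeyError(f"edge {edge} not in mesh")
    types = [mesh.cells[cid].cell_type for cid in cids]
    if len(types) == 1:
        return params.lambda_for(types[0])
    base = 0.5 * (params.lambda_for(types[0]) + params.lambda_for(types[1]))
    if contractility_active and types[0] != types[1]:
        return params.mu * base
    return base


@dataclass
class CompiledMesh:
    """Compact array view of a TissueMesh for the kernel."""

    vids: np.ndarray  # compact index -> vertex id
    pos: np.ndarray  # (V, 2), a copy; scatter back with sync_positions
    mobile: np.ndarray
    cell_order: list  # compact cell index -> cell id
    cstart: np.ndarray
    cverts: np.ndarray
    gamma_c: np.ndarray
    abn: np.ndarray
    edge_keys: list  # compact edge index -> (vid_min, vid_max)
    edge_v: np.ndarray
    edge_lam: np.ndarray
    edge_interior: np.ndarray
    idx_of: dict = field(default_factory=dict)

    def sync_positions(self, mesh: TissueMesh) -> None:
        mesh.vertices[self.vids] = self.pos


def compile_mesh(
    mesh: TissueMesh, params: MechanicalParams, contractility_active: bool = True
) -> CompiledMesh:
    vids = np.flatnonzero(mesh.vertex_alive)
    idx_of = {int(v): i for i, v in enumerate(vids)}
    pos = mesh.vertices[vids].copy()
    mobile = ~mesh.fixed[vids]
    cell_order = mesh.cell_ids()
    cstart = np.zeros(len(cell_order) + 1, dtype=np.int64)
    cverts_list: list[int] = []
    gamma_c = np.empty(len(cell_order))
    abn = np.zeros(len(cell_order), dtype=bool)
    for i, cid in enumerate(cell_order):
        loop = mesh.loops[cid]
        cverts_list.extend(idx_of[v] for v in loop)
        cstart[i + 1] = len(cverts_list)
        rec = mesh.cells[cid]
        gamma_c[i] = params.gamma_for(rec.cell_type)
        abn[i] = rec.cell_type == ABNORMAL
    cverts = np.asarray(cverts_list, dtype=np.int64)
    edge_keys = sorted(mesh.edge_map())
    edge_v = np.empty((len(edge_keys), 2), dtype=np.int64)
    edge_lam = np.empty(len(edge_keys))
    edge_interior = np.zeros(len(edge_keys), dtype=bool)
    em = mesh.edge_map()
    for k, key in enumerate(edge_keys):
        edge_v[k, 0] = idx_of[key[0]]
        edge_v[k, 1] = idx_of[key[1]]
        edge_lam[k] = edge_line_tension(mesh, key, params, contractility_active)
        edge_interior[k] = len(em[key]) == 2
    return CompiledMesh(
        vids=vids,
        pos=pos,
        mobile=mobile,
        cell_order=cell_order,
        cstart=cstart,
        cverts=cverts,
        gamma_c=gamma_c,
        abn=abn,
        edge_keys=edge_keys,
        edge_v=edge_v,
        edge_lam=edge_lam,
        edge_interior=edge_interior,
        idx_of=idx_of,
    )


def _target_areas(
    mesh: TissueMesh, cell_order: list, t_now: float, cycle_params: CellCycleParams | None
) -> np.ndarray:
    cp = cycle_params if cycle_params is not None else CellCycleParams()
    return np.array([mitotic_target_area(mesh.cells[cid], t_now, cp) for cid in cell_order])


def total_energy(
    mesh: TissueMesh,
    params: MechanicalParams,
    cycle_params: CellCycleParams | None = None,
    t_now: float = 0.0,
    contractility_active: bool = True,
) -> float:
    cm = compile_mesh(mesh, params, contractility_active)
    a0 = _target_areas(mesh, cm.cell_order, t_now, cycle_params)
    return float(
        _kernel.energy_arrays(cm.pos, cm.cstart, cm.cverts, cm.gamma_c, a0, cm.edge_v, cm.edge_lam)
    )


def vertex_forces(
    mesh: TissueMesh,
    params: MechanicalParams,
    cycle_params: CellCycleParams | None = None,
    t_now: float = 0.0,
    contractility_active: bool = True,
) -> np.ndarray:
    """F_i = -dU/dr_i for every vertex slot; zero on dead and fixed vertices."""
    cm = compile_mesh(mesh, params, contractility_active)
    a0 = _target_areas(mesh, cm.cell_order, t_now, cycle_params)
    areas = np.empty(len(cm.cell_order))
    perims = np.empty(len(cm.cell_order))
    _kernel.geometry(cm.pos, cm.cstart, cm.cverts, areas, perims)
    frc = np.empty_like(cm.pos)
    _kernel.forces_into(
        cm.pos, cm.cstart, cm.cverts, cm.gamma_c, areas, perims, a0, cm.edge_v, cm.edge_lam, frc
    )
    frc[~cm.mobile] = 0.0
    out = np.zeros_like(mesh.vertices)
    out[cm.vids] = frc
    return out


def euler_step(
    mesh: TissueMesh,
    params: MechanicalParams,
    cycle_params: CellCycleParams | None = None,
    t_now: float = 0.0,
    contractility_active: bool = True,
) -> TissueMesh:
    """One explicit Euler step r <- r + dt * F on mobile vertices (in place)."""
    frc = vertex_forces(mesh, params, cycle_params, t_now, contractility_active)
    mob = mesh.vertex_alive & ~mesh.fixed
    mesh.vertices[mob] += params.dt * frc[mob]
    return mesh
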