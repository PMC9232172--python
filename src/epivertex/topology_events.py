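"""T1 edge reconnection, T2 cell removal, and cell division surgery.

All operations preserve mesh validity: loops stay simple, counter-clockwise
and >= 3 vertices; interior edges keep exactly two incident cells.  An
operation that would violate these is skipped and logged rather than
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cell_cycle import CellCycleParams, division_trigger, draw_cycle_threshold
from .mesh_core import (
    INTERPHASE,
    CellRecord,
    TissueMesh,
    polygon_centroid,
    polygon_second_moment,
)

__all__ = [
    "EventRecord",
    "EventLog",
    "TopologyError",
    "apply_t1",
    "apply_t2",
    "divide_cell",
    "resolve_events",
    "POST_T1_LENGTH_FACTOR",
]

# fresh edge length after a T1, in units of theta_T1; > 1 avoids immediate retrigger
POST_T1_LENGTH_FACTOR = 1.5


class TopologyError(RuntimeError):
    """Raised when a surgery cannot be applied without breaking invariants."""


@dataclass
class EventRecord:
    time: float
    kind: str  # "T1" | "T2" | "division" | "skip"
    cell_ids: tuple
    details: dict = field(default_factory=dict)


class EventLog:
    def __init__(self):
        self.records: list[EventRecord] = []

    def append(self, time: float, kind: str, cell_ids, **details) -> None:
        if self.records and time < self.records[-1].time - 1e-12:
            raise ValueError("event times must be non-decreasing")
        self.records.append(EventRecord(time, kind, tuple(cell_ids), details))

    def count(self, kind: str) -> int:
        return sum(1 for r in self.records if r.kind == kind)

    def __len__(self):
        return len(self.records)

    def to_rows(self) -> list[dict]:
        return [
            {"time": r.time, "kind": r.kind, "cell_ids": ";".join(map(str, r.cell_ids)), **r.details}
            for r in self.records
        ]


def _other_cell(mesh: TissueMesh, v1: int, v2: int, not_this: int):
    key = (v1, v2) if v1 < v2 else (v2, v1)
    for cid in mesh.edge_map().get(key, []):
        if cid != not_this:
            return cid
    return None


def _vertex_degree(mesh: TissueMesh, vid: int) -> int:
    return sum(1 for loop in mesh.loops.values() if vid in loop)


def apply_t1(mesh: TissueMesh, edge: tuple[int, int], theta_t1: float) -> None:
    """Reconnect a short interior edge.

    The two edge-incident cells lose the edge; the two vertex-adjacent cells
    gain it.  The fresh edge is perpendicular to the old one through its
    midpoint, with length POST_T1_LENGTH_FACTOR * theta_t1.

    Raises TopologyError when the reconnection would create an invalid cell
    (< 3 sides, high-degree endpoint, or degenerate adjacency).
    """
    v1, v2 = edge
    key = (v1, v2) if v1 < v2 else (v2, v1)
    cids = mesh.edge_map().get(key)
    if cids is None or len(cids) != 2:
        raise TopologyError(f"edge {edge} is not an interior edge")
    # alpha: the cell whose CCW loop traverses a -> b
    alpha = beta = None
    a = b = None
    for cid in cids:
        loop = mesh.loops[cid]
        n = len(loop)
        for i in range(n):
            if loop[i] == key[0] and loop[(i + 1) % n] == key[1]:
                alpha, a, b = cid, key[0], key[1]
            elif loop[i] == key[1] and loop[(i + 1) % n] == key[0]:
                beta = cid
    if alpha is None or beta is None:
        raise TopologyError(f"edge {edge}: inconsistent loop orientations")
    if mesh.fixed[a] or mesh.fixed[b]:
        raise TopologyError("T1 on an immobilized (wall) vertex")
    if len(mesh.loops[alpha]) < 4 or len(mesh.loops[beta]) < 4:
        raise TopologyError("T1 would create a cell with fewer than 3 sides")
    if _vertex_degree(mesh, a) > 3 or _vertex_degree(mesh, b) > 3:
        raise TopologyError("T1 endpoint has degree > 3")

    la, lb = mesh.loops[alpha], mesh.loops[beta]
    ia, ib = la.index(a), lb.index(b)
    p_a = la[ia - 1]
    n_b = la[(la.index(b) + 1) % len(la)]
    n_a = lb[(lb.index(a) + 1) % len(lb)]
    p_b = lb[ib - 1]
    gamma = _other_cell(mesh, p_a, a, alpha)  # third cell at a
    delta = _other_cell(mesh, b, n_b, alpha)  # third cell at b
    if gamma is None and delta is None:
        raise TopologyError("T1 with no receiving cell on either side")
    if gamma is not None and delta is not None and gamma == delta:
        raise TopologyError("T1 receiving cells coincide")
    if gamma is not None and b in mesh.loops[gamma]:
        raise TopologyError("receiving cell already contains far endpoint")
    if delta is not None and a in mesh.loops[delta]:
        raise TopologyError("receiving cell already contains far endpoint")

    # geometry: a moves to alpha's side (left of a->b), b to beta's side
    pa, pb = mesh.vertices[a], mesh.vertices[b]
    m = 0.5 * (pa + pb)
    d = pb - pa
    nd = np.hypot(d[0], d[1])
    if nd == 0:
        raise TopologyError("zero-length edge")
    perp = np.array([-d[1], d[0]]) / nd  # rot90 = toward alpha's interior
    h = 0.5 * POST_T1_LENGTH_FACTOR * theta_t1
    mesh.vertices[a] = m + h * perp
    mesh.vertices[b] = m - h * perp

    la.remove(b)
    lb.remove(a)
    if gamma is not None:
        lg = mesh.loops[gamma]
        lg.insert(lg.index(a), b)  # ... n_a, b, a, p_a ...
    if delta is not None:
        ld = mesh.loops[delta]
        ld.insert(ld.index(b), a)  # ... n_b, a, b, p_b ...
    mesh._invalidate()


def apply_t2(mesh: TissueMesh, cell_id: int, absorb_area: float = 0.0) -> tuple[int, list[int]]:
    """Remove a small cell, merging its vertices into one at its centroid.

    When removing the focal cell would leave a neighbor with < 3 sides (or
    pinched in two places) and that neighbor's area is <= ``absorb_area``,
    the neighbor is collapsed together with it; this resolves clumps of
    mutually adjacent vanishing triangles at the end of an elimination.
    With the default absorb_area = 0 exactly one cell is removed.

    Returns (merged vertex id, removed cell ids).  Raises TopologyError
    when the removal cannot keep every surviving loop valid.
    """
    if cell_id not in mesh.loops:
        raise TopologyError(f"unknown cell {cell_id}")
    if any(mesh.fixed[v] for v in mesh.loops[cell_id]):
        raise TopologyError(f"T2 of cell {cell_id} would move a wall vertex")
    removal = {cell_id}
    w = -1  # placeholder id, patched after allocation
    while True:
        vset = {v for c in removal for v in mesh.loops[c]}
        new_loops: dict[int, list[int]] = {}
        grew = False
        for cid, other in mesh.loops.items():
            if cid in removal or not vset & set(other):
                continue
            repl = [w if v in vset else v for v in other]
            dedup: list[int] = []
            for v in repl:
                if not dedup or dedup[-1] != v:
                    dedup.append(v)
            if len(dedup) > 1 and dedup[0] == dedup[-1]:
                dedup.pop()
            if dedup.count(w) != 1 or len(dedup) < 3:
                if mesh.cell_area(cid) <= absorb_area and not any(mesh.fixed[v] for v in other):
                    removal.add(cid)
                    grew = True
                    break
                kind = "pinch" if dedup.count(w) != 1 else "degenerate"
                raise TopologyError(f"T2 of cell {cell_id} would {kind} neighbor {cid}")
            new_loops[cid] = dedup
        if not grew:
            break
    if len(removal) == len(mesh.loops):
        raise TopologyError("T2 would remove the whole tissue")
    cen = np.mean([mesh.vertices[v] for v in vset], axis=0)
    fixed = any(mesh.fixed[v] for v in vset)
    wid = mesh.add_vertex(cen, fixed=fixed)
    for cid, nl in new_loops.items():
        mesh.loops[cid] = [wid if v == w else v for v in nl]
    for v in vset:
        mesh.kill_vertex(v)
    for c in removal:
        mesh.remove_cell(c)
    return wid, sorted(removal)


def _division_crossings(coords: np.ndarray, cen: np.ndarray, theta: float, eps: float = 0.05):
    """Edge indices and points where the line through cen at angle theta cuts the polygon."""
    d = np.array([math.cos(theta), math.sin(theta)])
    rel = coords - cen
    s = d[0] * rel[:, 1] - d[1] * rel[:, 0]  # signed distance (up to scale) from the line
    n = len(coords)
    hits = []
    for i in range(n):
        j = (i + 1) % n
        if (s[i] > 0) == (s[j] > 0) or s[i] == s[j]:
            continue
        frac = s[i] / (s[i] - s[j])
        if frac < eps or frac > 1 - eps:
            return None  # too close to an existing vertex; caller resamples
        hits.append((i, coords[i] + frac * (coords[j] - coords[i])))
    if len(hits) != 2:
        return None
    return hits


def division_orientation(
    mesh: TissueMesh, cell_id: int, rule: str, rng: np.random.Generator
) -> float:
    if rule == "long_axis":
        m2 = polygon_second_moment(mesh.loop_coords(cell_id))
        evals, evecs = np.linalg.eigh(m2)
        long_axis = evecs[:, int(np.argmax(evals))]
        return math.atan2(long_axis[1], long_axis[0]) + math.pi / 2.0
    return float(rng.uniform(0.0, math.pi))


def divide_cell(
    mesh: TissueMesh,
    cell_id: int,
    cycle_params: CellCycleParams,
    rng: np.random.Generator,
    max_retries: int = 12,
) -> tuple[int, int]:
    """Split a cell by a line through its centroid; returns the daughter ids.

    The first orientation comes from the configured rule (uniform-random or
    perpendicular to the long axis); degenerate cuts are resampled uniformly
    up to ``max_retries`` times, then TopologyError is raised.
    """
    if cell_id not in mesh.loops:
        raise TopologyError(f"unknown cell {cell_id}")
    loop = mesh.loops[cell_id]
    coords = mesh.loop_coords(cell_id)
    cen = polygon_centroid(coords)
    hits = None
    theta = division_orientation(mesh, cell_id, cycle_params.orientation_rule, rng)
    for _ in range(max_retries):
        hits = _division_crossings(coords, cen, theta)
        if hits is not None:
            break
        theta = float(rng.uniform(0.0, math.pi))
    if hits is None:
        raise TopologyError(f"division of cell {cell_id}: no clean two-edge cut found")
    (i1, pt1), (i2, pt2) = hits

    n = len(loop)

    def on_wall(i):  # new vertex on a fully immobilized edge stays immobilized
        return bool(mesh.fixed[loop[i]] and mesh.fixed[loop[(i + 1) % n]])

    w1 = mesh.add_vertex(pt1, fixed=on_wall(i1))
    w2 = mesh.add_vertex(pt2, fixed=on_wall(i2))
    # insert the new vertex into the neighbor sharing each crossed edge
    for (i, w) in ((i1, w1), (i2, w2)):
        u, v = loop[i], loop[(i + 1) % n]
        other = _other_cell(mesh, u, v, cell_id)
        if other is not None:
            lo = mesh.loops[other]
            # neighbor traverses v -> u; insert w between them
            iu = lo.index(u)
            if lo[iu - 1] != v:
                raise TopologyError("inconsistent neighbor orientation at crossed edge")
            lo.insert(iu, w)
    # daughters (both CCW by construction)
    d1_loop = [w1] + [loop[k % n] for k in range(i1 + 1, i2 + 1)] + [w2]
    d2_loop = [w2] + [loop[k % n] for k in range(i2 + 1, i1 + 1 + n)] + [w1]
    mother = mesh.cells[cell_id]
    mesh.remove_cell(cell_id)
    daughters = []
    for dl in (d1_loop, d2_loop):
        rec = CellRecord(
            cell_id=-1,
            cell_type=mother.cell_type,
            clock=0.0,
            phase=INTERPHASE,
            cycle_threshold=draw_cycle_threshold(mother.cell_type, cycle_params, rng),
        )
        did = mesh.add_cell(dl, rec)
        mesh.cells[did].area_at_birth = mesh.cell_area(did)
        daughters.append(did)
    return tuple(daughters)


def resolve_events(
    mesh: TissueMesh,
    theta_t1: float,
    theta_t2: float,
    cycle_params: CellCycleParams,
    rng: np.random.Generator,
    t_now: float = 0.0,
    log: EventLog | None = None,
    max_iterations: int = 10,
    skip_edges: set | None = None,
    skip_cells: set | None = None,
) -> EventLog:
    """Scan and apply T1 (shortest first), T2 (smallest first), then divisions.

    Re-scans after every applied event until no candidates remain or the
    iteration cap is hit.  Unappliable candidates are logged as "skip" and
    remembered in ``skip_edges`` / ``skip_cells`` (caller-owned cooldowns).
    """
    if log is None:
        log = EventLog()
    skip_edges = skip_edges if skip_edges is not None else set()
    skip_cells = skip_cells if skip_cells is not None else set()
    for _ in range(max_iterations):
        acted = False
        # --- T1, shortest first
        t1_cands = sorted(
            (
                e
                for e in mesh.interior_edges()
                if e not in skip_edges
                and not (mesh.fixed[e[0]] or mesh.fixed[e[1]])  # wall vertices never reconnect
                and mesh.edge_length(e) < theta_t1
            ),
            key=mesh.edge_length,
        )
        for e in t1_cands:
            cells_of_edge = tuple(mesh.edge_map()[e])
            try:
                apply_t1(mesh, e, theta_t1)
                log.append(t_now, "T1", cells_of_edge, edge=e)
                acted = True
                break
            except TopologyError as exc:
                skip_edges.add(e)
                log.append(t_now, "skip", cells_of_edge, reason=str(exc))
        if acted:
            continue
        # --- T2, smallest first
        t2_cands = sorted(
            (
                c
                for c in mesh.cell_ids()
                if c not in skip_cells
                and not any(mesh.fixed[v] for v in mesh.loops[c])  # wall cells never removed
                and mesh.cell_area(c) < theta_t2
            ),
            key=mesh.cell_area,
        )
        for c in t2_cands:
            ctype = mesh.cells[c].cell_type
            try:
                pos = mesh.cell_centroid(c)
                _, removed = apply_t2(mesh, c, absorb_area=10.0 * theta_t2)
                log.append(t_now, "T2", removed, cell_type=ctype, x=float(pos[0]), y=float(pos[1]))
                acted = True
                break
            except TopologyError as exc:
                skip_cells.add(c)
                log.append(t_now, "skip", (c,), reason=str(exc))
        if acted:
            continue
        # --- divisions
        for c in mesh.cell_ids():
            if c in skip_cells:
                continue
            rec = mesh.cells[c]
            if division_trigger(rec, mesh.cell_area(c), cycle_params):
                try:
                    d1, d2 = divide_cell(mesh, c, cycle_params, rng)
                    log.append(t_now, "division", (c, d1, d2), cell_type=rec.cell_type)
                    acted = True
                    break
                except TopologyError as exc:
                    skip_cells.add(c)
                    log.append(t_now, "skip", (c,), reason=str(exc))
        if not acted:
            break
    return log
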