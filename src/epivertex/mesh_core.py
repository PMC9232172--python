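"""Planar polygonal mesh for the apical cell network.

The tissue is a simply-connected patch of polygonal cells.  Each cell is an
ordered, counter-clockwise loop of vertex ids into a shared vertex table.
Interior edges are shared by exactly two cells, boundary edges by one.
All lengths are in the nondimensional units of the energy function
(preferred cell area = 1).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CellRecord",
    "TissueMesh",
    "build_hexagonal_tissue",
    "cell_geometry",
    "validate_mesh",
    "write_snapshot",
    "read_snapshot",
]

NORMAL = "normal"
ABNORMAL = "abnormal"

INTERPHASE = "interphase"
MITOTIC = "mitotic"


@dataclass
class CellRecord:
    """Per-cell identity and cell-cycle state."""

    cell_id: int
    cell_type: str = NORMAL
    clock: float = 0.0
    phase: str = INTERPHASE
    cycle_threshold: float = math.inf  # drawn division-clock threshold tau*(1+u)
    mitosis_entry_time: float = math.nan
    area_at_mitosis_entry: float = math.nan
    area_at_birth: float = math.nan

    def copy(self) -> "CellRecord":
        return replace(self)


class TissueMesh:
    """Vertices + ordered cell loops + per-cell records.

    Vertices live in a growing (V, 2) array; removed vertices are marked
    dead and their slots are never reused within a mesh lifetime (ids stay
    stable for event logs and snapshots).
    """

    def __init__(self, boundary_condition: str = "free"):
        if boundary_condition not in ("free", "fixed_wall"):
            raise ValueError(f"unknown boundary_condition {boundary_condition!r}")
        self.boundary_condition = boundary_condition
        self.vertices = np.empty((0, 2), dtype=float)
        self.vertex_alive = np.empty(0, dtype=bool)
        self.fixed = np.empty(0, dtype=bool)
        self.loops: dict[int, list[int]] = {}
        self.cells: dict[int, CellRecord] = {}
        self._next_cell_id = 0
        self._edge_cache: dict[tuple[int, int], list[int]] | None = None

    # ------------------------------------------------------------------ topology bookkeeping

    def _invalidate(self) -> None:
        self._edge_cache = None

    def add_vertex(self, xy, fixed: bool = False) -> int:
        vid = self.vertices.shape[0]
        self.vertices = np.vstack([self.vertices, np.asarray(xy, dtype=float)])
        self.vertex_alive = np.append(self.vertex_alive, True)
        self.fixed = np.append(self.fixed, bool(fixed))
        self._invalidate()
        return vid

    def add_cell(self, loop: list[int], record: CellRecord | None = None) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        self.loops[cid] = list(loop)
        rec = record.copy() if record is not None else CellRecord(cell_id=cid)
        rec.cell_id = cid
        self.cells[cid] = rec
        self._invalidate()
        return cid

    def remove_cell(self, cell_id: int) -> None:
        del self.loops[cell_id]
        del self.cells[cell_id]
        self._invalidate()

    def kill_vertex(self, vid: int) -> None:
        self.vertex_alive[vid] = False
        self._invalidate()

    @property
    def n_cells(self) -> int:
        return len(self.loops)

    @property
    def n_vertices(self) -> int:
        return int(self.vertex_alive.sum())

    def cell_ids(self) -> list[int]:
        return sorted(self.loops)

    # ------------------------------------------------------------------ edges

    def edge_map(self) -> dict[tuple[int, int], list[int]]:
        """Map (min_vid, max_vid) -> ids of incident cells."""
        if self._edge_cache is None:
            em: dict[tuple[int, int], list[int]] = {}
            for cid, loop in self.loops.items():
                n = len(loop)
                for i in range(n):
                    a, b = loop[i], loop[(i + 1) % n]
                    key = (a, b) if a < b else (b, a)
                    em.setdefault(key, []).append(cid)
            self._edge_cache = em
        return self._edge_cache

    def interior_edges(self) -> list[tuple[int, int]]:
        return [e for e, cs in self.edge_map().items() if len(cs) == 2]

    def boundary_edges(self) -> list[tuple[int, int]]:
        return [e for e, cs in self.edge_map().items() if len(cs) == 1]

    def boundary_vertices(self) -> set[int]:
        out: set[int] = set()
        for a, b in self.boundary_edges():
            out.add(a)
            out.add(b)
        return out

    def vertex_cells(self, vid: int) -> list[int]:
        return [cid for cid, loop in self.loops.items() if vid in loop]

    def edge_length(self, edge: tuple[int, int]) -> float:
        a, b = edge
        v = self.vertices
        return math.hypot(v[a, 0] - v[b, 0], v[a, 1] - v[b, 1])

    # ------------------------------------------------------------------ geometry

    def loop_coords(self, cell_id: int) -> np.ndarray:
        return self.vertices[np.asarray(self.loops[cell_id], dtype=int)]

    def cell_area(self, cell_id: int) -> float:
        loop = self.loops[cell_id]
        v = self.vertices
        x0, y0 = v[loop[-1], 0], v[loop[-1], 1]
        s = 0.0
        for vid in loop:
            x1, y1 = v[vid, 0], v[vid, 1]
            s += x0 * y1 - x1 * y0
            x0, y0 = x1, y1
        return 0.5 * s

    def cell_perimeter(self, cell_id: int) -> float:
        loop = self.loops[cell_id]
        v = self.vertices
        x0, y0 = v[loop[-1], 0], v[loop[-1], 1]
        s = 0.0
        for vid in loop:
            x1, y1 = v[vid, 0], v[vid, 1]
            s += math.hypot(x1 - x0, y1 - y0)
            x0, y0 = x1, y1
        return s

    def cell_centroid(self, cell_id: int) -> np.ndarray:
        return polygon_centroid(self.loop_coords(cell_id))

    def abnormal_ids(self) -> list[int]:
        return [cid for cid in self.cell_ids() if self.cells[cid].cell_type == ABNORMAL]

    def copy(self) -> "TissueMesh":
        m = TissueMesh(self.boundary_condition)
        m.vertices = self.vertices.copy()
        m.vertex_alive = self.vertex_alive.copy()
        m.fixed = self.fixed.copy()
        m.loops = {cid: list(loop) for cid, loop in self.loops.items()}
        m.cells = {cid: rec.copy() for cid, rec in self.cells.items()}
        m._next_cell_id = self._next_cell_id
        return m


# ---------------------------------------------------------------------- geometry helpers


def shoelace_area(coords: np.ndarray) -> float:
    """Signed area of an ordered loop (positive = counter-clockwise)."""
    x, y = coords[:, 0], coords[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(coords: np.ndarray) -> np.ndarray:
    x, y = coords[:, 0], coords[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-14:
        return coords.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_second_moment(coords: np.ndarray) -> np.ndarray:
    """2x2 second-moment (covariance) tensor of the polygon area about its centroid."""
    c = polygon_centroid(coords)
    p = coords - c
    xn = np.roll(p, -1, axis=0)
    cross = p[:, 0] * xn[:, 1] - xn[:, 0] * p[:, 1]
    ixx = np.sum(cross * (p[:, 1] ** 2 + p[:, 1] * xn[:, 1] + xn[:, 1] ** 2)) / 12.0
    iyy = np.sum(cross * (p[:, 0] ** 2 + p[:, 0] * xn[:, 0] + xn[:, 0] ** 2)) / 12.0
    ixy = np.sum(
        cross * (p[:, 0] * xn[:, 1] + 2 * p[:, 0] * p[:, 1] + 2 * xn[:, 0] * xn[:, 1] + xn[:, 0] * p[:, 1])
    ) / 24.0
    a = 0.5 * cross.sum()
    sign = 1.0 if a >= 0 else -1.0
    return sign * np.array([[iyy, ixy], [ixy, ixx]])


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def loop_is_simple(coords: np.ndarray) -> bool:
    n = len(coords)
    if n < 3:
        return False
    for i in range(n):
        for j in range(i + 1, n):
            # skip adjacent segments (share a vertex)
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(coords[i], coords[(i + 1) % n], coords[j], coords[(j + 1) % n]):
                return False
    return True


# ---------------------------------------------------------------------- operations


def build_hexagonal_tissue(
    n_cells_target: int,
    edge_length: float,
    boundary_condition: str = "free",
) -> TissueMesh:
    """Roughly circular patch of regular hexagons centered at the origin.

    The patch is built ring by ring (cell counts 1 + 3k(k+1)); the ring
    count is chosen to minimize the distance to ``n_cells_target``.  Under
    ``fixed_wall`` boundary vertices are flagged immobile.
    """
    if n_cells_target < 1:
        raise ValueError("n_cells_target must be >= 1")
    if edge_length <= 0:
        raise ValueError("edge_length must be > 0")

    def ring_count(k: int) -> int:
        return 1 + 3 * k * (k + 1)

    k = 0
    while ring_count(k + 1) <= n_cells_target:
        k += 1
    if abs(ring_count(k + 1) - n_cells_target) < abs(ring_count(k) - n_cells_target):
        k += 1

    e = float(edge_length)
    # hexagon centers on a triangular lattice with spacing sqrt(3)*e
    centers = []
    s = math.sqrt(3.0) * e
    a1 = np.array([s, 0.0])
    a2 = np.array([s / 2.0, s * math.sqrt(3.0) / 2.0])
    for q in range(-k, k + 1):
        for r in range(max(-k, -q - k), min(k, -q + k) + 1):
            centers.append(q * a1 + r * a2)

    mesh = TissueMesh(boundary_condition)
    vert_index: dict[tuple[int, int], int] = {}
    tol = e * 1e-6

    def get_vertex(xy) -> int:
        key = (round(xy[0] / tol), round(xy[1] / tol))
        # tolerate off-by-one rounding of merged coordinates
        for dk in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
            kk = (key[0] + dk[0], key[1] + dk[1])
            if kk in vert_index:
                return vert_index[kk]
        vid = mesh.add_vertex(xy)
        vert_index[key] = vid
        return vid

    # pointy-top hexagon: vertices at angles 30 + 60 j (degrees), circumradius e
    angles = [math.radians(30 + 60 * j) for j in range(6)]
    for c in centers:
        loop = [get_vertex((c[0] + e * math.cos(t), c[1] + e * math.sin(t))) for t in angles]
        mesh.add_cell(loop)

    if boundary_condition == "fixed_wall":
        for vid in mesh.boundary_vertices():
            mesh.fixed[vid] = True
    return mesh


def cell_geometry(mesh: TissueMesh, cell_id: int) -> dict:
    """Area (shoelace), perimeter, and centroid of one cell."""
    if cell_id not in mesh.loops:
        raise KeyError(f"unknown cell_id {cell_id}")
    return {
        "area": mesh.cell_area(cell_id),
        "perimeter": mesh.cell_perimeter(cell_id),
        "centroid": mesh.cell_centroid(cell_id),
    }


def validate_mesh(mesh: TissueMesh) -> list[str]:
    """Check all mesh invariants; returns a list of violation strings."""
    report: list[str] = []
    for cid, loop in mesh.loops.items():
        if len(loop) < 3:
            report.append(f"cell {cid}: fewer than 3 vertices")
            continue
        if len(set(loop)) != len(loop):
            report.append(f"cell {cid}: degenerate loop (repeated vertex)")
            continue
        for vid in loop:
            if vid >= len(mesh.vertex_alive) or not mesh.vertex_alive[vid]:
                report.append(f"cell {cid}: references dead/unknown vertex {vid}")
        coords = mesh.loop_coords(cid)
        a = shoelace_area(coords)
        if a <= 0:
            report.append(f"cell {cid}: non-positive area {a:.3g} (clockwise or degenerate loop)")
        elif not loop_is_simple(coords):
            report.append(f"cell {cid}: self-intersecting loop")
    for edge, cids in mesh.edge_map().items():
        if len(cids) > 2:
            report.append(f"edge {edge}: incidence violation ({len(cids)} cells)")
    if cids_mismatch := set(mesh.loops) ^ set(mesh.cells):
        report.append(f"loop/record mismatch for cells {sorted(cids_mismatch)}")
    return report


# ---------------------------------------------------------------------- snapshot I/O

SNAPSHOT_VERSION = 1


def write_snapshot(mesh: TissueMesh, path, time: float = 0.0, params_hash: str = "") -> None:
    """Versioned structured-text snapshot (lossless float round trip via repr)."""
    buf = io.StringIO()
    buf.write("# epivertex mesh snapshot\n")
    buf.write(f"format_version: {SNAPSHOT_VERSION}\n")
    buf.write(f"time: {time!r}\n")
    buf.write(f"params_hash: {params_hash}\n")
    buf.write(f"boundary_condition: {mesh.boundary_condition}\n")
    alive = [v for v in range(len(mesh.vertex_alive)) if mesh.vertex_alive[v]]
    buf.write(f"vertices: {len(alive)}\n")
    for vid in alive:
        x, y = (float(c) for c in mesh.vertices[vid])
        buf.write(f"{vid} {x!r} {y!r} {int(mesh.fixed[vid])}\n")
    buf.write(f"cells: {len(mesh.loops)}\n")
    for cid in mesh.cell_ids():
        r = mesh.cells[cid]
        loop = " ".join(str(v) for v in mesh.loops[cid])
        state = " ".join(
            repr(float(v))
            for v in (r.clock, r.cycle_threshold, r.mitosis_entry_time, r.area_at_mitosis_entry, r.area_at_birth)
        )
        buf.write(f"{cid} {r.cell_type} {r.phase} {state} {len(mesh.loops[cid])} {loop}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


class SnapshotError(ValueError):
    pass


def read_snapshot(path) -> TissueMesh:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    it = iter(ln for ln in lines if ln and not ln.startswith("#"))

    def expect(key: str) -> str:
        ln = next(it, None)
        if ln is None or not ln.startswith(key + ":"):
            raise SnapshotError(f"expected '{key}:' record, got {ln!r}")
        return ln.split(":", 1)[1].strip()

    version = int(expect("format_version"))
    if version != SNAPSHOT_VERSION:
        raise SnapshotError(f"unsupported snapshot version {version}")
    expect("time")
    expect("params_hash")
    bc = expect("boundary_condition")
    mesh = TissueMesh(bc)
    n_verts = int(expect("vertices"))
    max_vid = -1
    rows = []
    for _ in range(n_verts):
        ln = next(it, None)
        if ln is None:
            raise SnapshotError("truncated vertex table")
        parts = ln.split()
        if len(parts) != 4:
            raise SnapshotError(f"malformed vertex record: {ln!r}")
        vid = int(parts[0])
        rows.append((vid, float(parts[1]), float(parts[2]), bool(int(parts[3]))))
        max_vid = max(max_vid, vid)
    mesh.vertices = np.zeros((max_vid + 1, 2))
    mesh.vertex_alive = np.zeros(max_vid + 1, dtype=bool)
    mesh.fixed = np.zeros(max_vid + 1, dtype=bool)
    for vid, x, y, fx in rows:
        mesh.vertices[vid] = (x, y)
        mesh.vertex_alive[vid] = True
        mesh.fixed[vid] = fx
    n_cells = int(expect("cells"))
    for _ in range(n_cells):
        ln = next(it, None)
        if ln is None:
            raise SnapshotError("truncated cell table")
        parts = ln.split()
        try:
            cid = int(parts[0])
            ctype, phase = parts[1], parts[2]
            if ctype not in (NORMAL, ABNORMAL):
                raise SnapshotError(f"unknown cell_type token {ctype!r} in record {ln!r}")
            if phase not in (INTERPHASE, MITOTIC):
                raise SnapshotError(f"unknown phase token {phase!r} in record {ln!r}")
            clock, thr, ment, marea, barea = (float(p) for p in parts[3:8])
            nv = int(parts[8])
            loop = [int(p) for p in parts[9 : 9 + nv]]
            if len(loop) != nv:
                raise SnapshotError(f"cell {cid}: loop shorter than declared")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, SnapshotError):
                raise
            raise SnapshotError(f"malformed cell record: {ln!r}") from exc
        mesh.loops[cid] = loop
        mesh.cells[cid] = CellRecord(
            cell_id=cid,
            cell_type=ctype,
            phase=phase,
            clock=clock,
            cycle_threshold=thr,
            mitosis_entry_time=ment,
            area_at_mitosis_entry=marea,
            area_at_birth=barea,
        )
        mesh._next_cell_id = max(mesh._next_cell_id, cid + 1)
    return mesh
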