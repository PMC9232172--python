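import math

import numpy as np
import pytest

from epivertex import mesh_core as mc
from epivertex import topology_events as te
from epivertex.cell_cycle import CellCycleParams
from epivertex.mesh_core import ABNORMAL, MITOTIC

from conftest import mark_central


def shrink_edge(mesh, edge, factor=0.001):
    mid = 0.5 * (mesh.vertices[edge[0]] + mesh.vertices[edge[1]])
    d = mesh.vertices[edge[1]] - mesh.vertices[edge[0]]
    mesh.vertices[edge[0]] = mid - 0.5 * factor * d
    mesh.vertices[edge[1]] = mid + 0.5 * factor * d
    mesh._invalidate()


def pick_full_interior_edge(mesh):
    """Interior edge whose endpoints both have three incident cells."""
    for e in mesh.interior_edges():
        if len(mesh.vertex_cells(e[0])) == 3 and len(mesh.vertex_cells(e[1])) == 3:
            return e
    raise AssertionError("no suitable edge")


class TestApplyT1:
    def test_reconnection_swaps_cell_pairs(self, patch19):
        edge = pick_full_interior_edge(patch19)
        old_pair = set(patch19.edge_map()[edge])
        a, b = edge
        gamma_delta = (set(patch19.vertex_cells(a)) | set(patch19.vertex_cells(b))) - old_pair
        shrink_edge(patch19, edge)
        te.apply_t1(patch19, edge, theta_t1=0.05)
        assert mc.validate_mesh(patch19) == []
        new_pair = set(patch19.edge_map()[(min(edge), max(edge))])
        assert new_pair == gamma_delta

    def test_side_count_bookkeeping(self, patch19):
        edge = pick_full_interior_edge(patch19)
        before = {c: len(patch19.loops[c]) for c in patch19.cell_ids()}
        shrink_edge(patch19, edge)
        te.apply_t1(patch19, edge, theta_t1=0.05)
        deltas = sorted(len(patch19.loops[c]) - before[c] for c in patch19.cell_ids())
        assert deltas.count(-1) == 2
        assert deltas.count(1) == 2
        assert all(d == 0 for d in deltas[2:-2])

    def test_counts_conserved(self, patch19):
        edge = pick_full_interior_edge(patch19)
        nc, nv = patch19.n_cells, patch19.n_vertices
        shrink_edge(patch19, edge)
        te.apply_t1(patch19, edge, theta_t1=0.05)
        assert patch19.n_cells == nc
        assert patch19.n_vertices == nv

    def test_fresh_edge_above_threshold(self, patch19):
        edge = pick_full_interior_edge(patch19)
        shrink_edge(patch19, edge)
        theta = 0.05
        te.apply_t1(patch19, edge, theta_t1=theta)
        assert patch19.edge_length(edge) == pytest.approx(te.POST_T1_LENGTH_FACTOR * theta)
        assert patch19.edge_length(edge) > theta

    def test_triangle_cell_rejected(self, patch19, solid_ground):
        # make a triangle by dividing, then try to T1 one of its edges
        cid = mark_central(patch19, 1)[0]
        rng = np.random.default_rng(0)
        cp = CellCycleParams()
        d1, d2 = te.divide_cell(patch19, cid, cp, rng)
        small = min((d1, d2), key=lambda c: len(patch19.loops[c]))
        # shrink every edge of a >=4-gon neighbour? instead directly target an edge of any triangle
        tri = None
        for c in patch19.cell_ids():
            if len(patch19.loops[c]) == 3:
                tri = c
                break
        if tri is None:
            pytest.skip("random cut produced no triangle")
        loop = patch19.loops[tri]
        edge = (loop[0], loop[1])
        if len(patch19.edge_map()[(min(edge), max(edge))]) != 2:
            pytest.skip("triangle edge on boundary")
        with pytest.raises(te.TopologyError):
            te.apply_t1(patch19, edge, theta_t1=0.05)

    def test_wall_vertex_rejected(self, solid_ground):
        mesh = mc.build_hexagonal_tissue(19, solid_ground.l_g, "fixed_wall")
        for e in mesh.interior_edges():
            if mesh.fixed[e[0]] or mesh.fixed[e[1]]:
                with pytest.raises(te.TopologyError):
                    te.apply_t1(mesh, e, theta_t1=0.05)
                return
        pytest.skip("no interior edge touching the wall")


class TestApplyT2:
    def test_removes_cell_and_merges_vertices(self, patch19):
        # divide the central cell to create a small cell, then remove it
        cid = mark_central(patch19, 1)[0]
        rng = np.random.default_rng(3)
        d1, d2 = te.divide_cell(patch19, cid, CellCycleParams(), rng)
        target = min((d1, d2), key=patch19.cell_area)
        nv_cell = len(patch19.loops[target])
        nc, nv = patch19.n_cells, patch19.n_vertices
        wid, removed = te.apply_t2(patch19, target)
        assert removed == [target]
        assert patch19.n_cells == nc - 1
        assert patch19.n_vertices == nv - (nv_cell - 1)
        assert mc.validate_mesh(patch19) == []

    def test_neighbors_lose_vertices(self, patch19):
        cid = mark_central(patch19, 1)[0]
        neighbors = {
            other
            for e, cs in patch19.edge_map().items()
            for other in cs
            if cid in cs and other != cid
        }
        before = {c: len(patch19.loops[c]) for c in neighbors}
        te.apply_t2(patch19, cid)
        for c in neighbors:
            assert len(patch19.loops[c]) == before[c] - 1
        assert mc.validate_mesh(patch19) == []

    def test_abnormal_count_decrements(self, patch19):
        cid = mark_central(patch19, 1)[0]
        n_before = len(patch19.abnormal_ids())
        te.apply_t2(patch19, cid)
        assert len(patch19.abnormal_ids()) == n_before - 1

    def test_merged_vertex_at_centroid(self, patch19):
        cid = mark_central(patch19, 1)[0]
        cen = patch19.cell_centroid(cid)
        wid, _ = te.apply_t2(patch19, cid)
        np.testing.assert_allclose(patch19.vertices[wid], cen, atol=1e-9)

    def test_wall_cell_rejected(self, solid_ground):
        mesh = mc.build_hexagonal_tissue(7, solid_ground.l_g, "fixed_wall")
        outer = max(mesh.cell_ids(), key=lambda c: np.linalg.norm(mesh.cell_centroid(c)))
        with pytest.raises(te.TopologyError):
            te.apply_t2(mesh, outer)


class TestDivideCell:
    def test_daughter_areas_sum_to_mother(self, patch19):
        cid = mark_central(patch19, 1)[0]
        area = patch19.cell_area(cid)
        d1, d2 = te.divide_cell(patch19, cid, CellCycleParams(), np.random.default_rng(0))
        assert patch19.cell_area(d1) + patch19.cell_area(d2) == pytest.approx(area, rel=1e-12)
        assert mc.validate_mesh(patch19) == []

    def test_hexagon_cut_through_opposite_edges(self):
        # a cut crossing two opposite edges leaves two 5-vertex daughters
        mesh = mc.build_hexagonal_tissue(1, 1.0)

        class FixedAngle:
            def uniform(self, lo, hi):
                return 0.0  # horizontal cut through opposite (left/right) edges

        d1, d2 = te.divide_cell(mesh, 0, CellCycleParams(), FixedAngle())
        assert sorted(len(mesh.loops[d]) for d in (d1, d2)) == [5, 5]
        assert mesh.cell_area(d1) == pytest.approx(mesh.cell_area(d2), rel=1e-9)

    def test_neighbors_gain_one_side(self, patch19):
        cid = mark_central(patch19, 1)[0]
        before = {c: len(patch19.loops[c]) for c in patch19.cell_ids() if c != cid}
        te.divide_cell(patch19, cid, CellCycleParams(), np.random.default_rng(1))
        after = {c: len(patch19.loops[c]) for c in before}
        gained = [c for c in before if after[c] == before[c] + 1]
        unchanged = [c for c in before if after[c] == before[c]]
        assert len(gained) == 2  # the two cells adjacent to the crossed edges
        assert len(gained) + len(unchanged) == len(before)

    def test_daughters_inherit_type_and_reset_clock(self, patch19):
        cid = mark_central(patch19, 1)[0]
        patch19.cells[cid].clock = 4.9
        d1, d2 = te.divide_cell(patch19, cid, CellCycleParams(), np.random.default_rng(2))
        for d in (d1, d2):
            rec = patch19.cells[d]
            assert rec.cell_type == ABNORMAL
            assert rec.clock == 0.0
            assert rec.phase == "interphase"
            assert 4.0 <= rec.cycle_threshold <= 6.0
            assert rec.area_at_birth == pytest.approx(patch19.cell_area(d))

    def test_long_axis_rule_cuts_short_axis(self):
        # an elongated rectangle must be cut across its long (x) axis
        mesh = mc.TissueMesh()
        vs = [mesh.add_vertex(p) for p in [(0, 0), (4, 0), (4, 1), (0, 1)]]
        cid = mesh.add_cell(vs)
        cp = CellCycleParams(orientation_rule="long_axis")
        d1, d2 = te.divide_cell(mesh, cid, cp, np.random.default_rng(0))
        # daughters should be the left and right halves: both areas 2
        assert mesh.cell_area(d1) == pytest.approx(2.0, rel=1e-6)
        cents = sorted(mesh.cell_centroid(d)[0] for d in (d1, d2))
        assert cents[0] == pytest.approx(1.0, abs=0.05)
        assert cents[1] == pytest.approx(3.0, abs=0.05)


class TestResolveEvents:
    def _cycle(self):
        return CellCycleParams()

    def test_no_candidates_no_change(self, patch19):
        before = {c: list(patch19.loops[c]) for c in patch19.cell_ids()}
        log = te.resolve_events(
            patch19, 1e-6, 1e-9, self._cycle(), np.random.default_rng(0), t_now=0.0
        )
        assert len(log) == 0
        assert {c: list(patch19.loops[c]) for c in patch19.cell_ids()} == before

    def test_two_disjoint_short_edges_both_fixed(self, solid_ground):
        mesh = mc.build_hexagonal_tissue(37, solid_ground.l_g)
        edges = []
        used = set()
        for e in mesh.interior_edges():
            cells = set(mesh.edge_map()[e])
            if (
                len(mesh.vertex_cells(e[0])) == 3
                and len(mesh.vertex_cells(e[1])) == 3
                and not (cells & used)
            ):
                edges.append(e)
                used |= cells | set(mesh.vertex_cells(e[0])) | set(mesh.vertex_cells(e[1]))
            if len(edges) == 2:
                break
        for e in edges:
            shrink_edge(mesh, e)
        theta = 0.05
        log = te.resolve_events(mesh, theta, 1e-9, self._cycle(), np.random.default_rng(0))
        assert log.count("T1") == 2
        assert mc.validate_mesh(mesh) == []

    def test_division_trigger_resolved(self, patch19):
        cid = mark_central(patch19, 1)[0]
        rec = patch19.cells[cid]
        rec.phase = MITOTIC
        rec.mitosis_entry_time = 0.0
        rec.area_at_mitosis_entry = patch19.cell_area(cid) / 2.01
        n0 = patch19.n_cells
        log = te.resolve_events(patch19, 1e-6, 1e-9, self._cycle(), np.random.default_rng(0))
        assert log.count("division") == 1
        assert patch19.n_cells == n0 + 1

    def test_event_log_times_monotone(self):
        log = te.EventLog()
        log.append(0.0, "T1", (1, 2))
        log.append(1.0, "T2", (3,))
        with pytest.raises(ValueError):
            log.append(0.5, "T1", (4, 5))
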