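"""Knot identification: simplification, Alexander determinants, relevance."""

import numpy as np
import pytest

from knotloop.params import ModelParams
from knotloop.state import RunOutcome
from knotloop.topology import (
    ClosedPolygon,
    KnotType,
    alexander_determinants,
    classify_knot,
    classify_polygon,
    close_chain,
    loop_relevance,
    parametric_knot,
    random_closed_polygon,
    simplify,
)

# determinant pairs of the symmetric Alexander polynomials evaluated at
# t = -1, -2:  0_1: 1;  3_1: t^2-t+1;  4_1: t^2-3t+1 (sign-normalized);
# 5_1: t^4-t^3+t^2-t+1;  5_2: 2t^2-3t+2
DET_TABLE = {
    "0_1": (1, 1),
    "3_1": (3, 7),
    "4_1": (5, 11),
    "5_1": (5, 31),
    "5_2": (7, 16),
}


class TestSimplify:
    def test_planar_convex_polygon_collapses_to_triangle(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        poly = ClosedPolygon(
            np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        )
        assert len(simplify(poly)) == 3

    def test_triangle_is_a_fixed_point(self):
        tri = ClosedPolygon(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float))
        out = simplify(tri)
        np.testing.assert_allclose(out.vertices, tri.vertices)

    def test_trefoil_reduction_preserves_type_and_is_nontrivial(self):
        poly = parametric_knot("3_1", 200, 0.0, 0)
        red = simplify(poly)
        assert 6 <= len(red) < 200
        assert alexander_determinants(red, seed=0) == DET_TABLE["3_1"]
        assert alexander_determinants(poly, seed=0) == DET_TABLE["3_1"]

    def test_marked_vertices_survive(self):
        poly = parametric_knot("3_1", 120, 0.0, 0)
        marked = ClosedPolygon(poly.vertices, marked_indices=(10, 80))
        red = simplify(marked)
        x, y = red.marked_indices
        np.testing.assert_allclose(red.vertices[x], poly.vertices[10])
        np.testing.assert_allclose(red.vertices[y], poly.vertices[80])


class TestAlexander:
    def test_unknotted_triangle(self):
        tri = ClosedPolygon(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.1]]))
        assert alexander_determinants(tri, seed=0) == (1, 1)

    @pytest.mark.parametrize("label", sorted(DET_TABLE))
    def test_parametric_fixture_determinants(self, label):
        poly = parametric_knot(label, 240, 0.0, 0)
        assert alexander_determinants(simplify(poly), seed=3) == DET_TABLE[label]

    @pytest.mark.parametrize("label", sorted(DET_TABLE))
    def test_projection_independence(self, label):
        poly = simplify(parametric_knot(label, 200, 0.03, 5))
        dets = {alexander_determinants(poly, seed=s) for s in range(20)}
        assert dets == {DET_TABLE[label]}

    def test_classify_table(self):
        assert classify_knot((3, 7)).label == "3_1"
        assert classify_knot((1, 1)).label == "0_1"
        assert classify_knot((9, 40)).label == "other"

    def test_reversal_invariance(self):
        for s in range(25):
            poly = random_closed_polygon(40, seed=s)
            rev = ClosedPolygon(poly.vertices[::-1].copy())
            assert classify_polygon(poly, seed=s).label == classify_polygon(rev, seed=s).label

    def test_simplification_invariance_on_random_polygons(self):
        """classify(simplify(P)) agrees with classifying P directly."""
        for s in range(60):
            poly = random_closed_polygon(26, seed=s)
            direct = classify_polygon(poly, seed=s, pre_simplify=False)
            reduced = classify_polygon(poly, seed=s + 1, pre_simplify=True)
            assert direct.label == reduced.label, f"seed {s}"

    def test_projection_stability_on_random_polygons(self):
        for s in range(150):
            poly = random_closed_polygon(60, seed=s)
            a = classify_polygon(poly, seed=s)
            b = classify_polygon(poly, seed=s + 10_000)
            assert a.label == b.label, f"seed {s}"


class TestParametricFixtures:
    def test_insufficient_vertices_rejected(self):
        with pytest.raises(ValueError):
            parametric_knot("5_1", 10, 0.0, 0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            parametric_knot("6_1", 100, 0.0, 0)

    def test_unknot_classifies_clean(self):
        assert classify_polygon(parametric_knot("0_1", 50, 0.0, 1)).label == "0_1"


class TestCloseChain:
    def _outcome(self, circ: bool):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pos = np.stack([np.cos(t), np.sin(t), 0.01 * np.sin(3 * t)], axis=1)
        return RunOutcome(
            final_positions=pos,
            circularized=circ,
            internal_loop_closed_at_end=False,
            censored=not circ,
            steps_elapsed=100,
            seed=0,
        )

    def test_polygon_from_circularized_run(self):
        params = ModelParams.chain(40, internal_pair=(8, 30))
        poly = close_chain(self._outcome(True), params)
        assert len(poly) == 40
        assert poly.marked_indices == (8, 30)

    def test_censored_run_rejected(self):
        with pytest.raises(ValueError):
            close_chain(self._outcome(False))


def _splice_trefoil_into_arc(scale=0.45):
    """A big ring with a trefoil tied entirely inside the marked segment."""
    knot = parametric_knot("3_1", 120, 0.0, 0).vertices
    # open the trefoil at its widest gap and scale it down
    knot = knot * scale / 3.0
    start, end = knot[0], knot[-1]
    # carrier circle: replace one arc with the opened trefoil
    t = np.linspace(np.pi * 0.25, 2 * np.pi * 0.95, 80)
    ring = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
    # translate the knot so its endpoints bridge the carrier gap
    a, b = ring[-1], ring[0]
    shift = (a + b) / 2 - (start + end) / 2
    knot = knot + shift
    verts = np.concatenate([ring, knot])
    x, y = len(ring) - 1, len(verts) - 1
    return ClosedPolygon(verts, marked_indices=(x, y))


class TestLoopRelevance:
    def test_knot_localized_inside_loop_is_irrelevant(self):
        poly = _splice_trefoil_into_arc()
        full = classify_polygon(poly, seed=2)
        assert full.label == "3_1"
        rel = loop_relevance(poly, full, seed=2)
        assert not rel.relevant
        assert rel.loop_ring.label == "3_1"
        assert rel.excised.label == "0_1"
        assert rel.consistent

    def test_knot_localized_outside_loop_is_irrelevant(self):
        poly = _splice_trefoil_into_arc()
        # swap the marked segment: same ring, marks bracketing the trivial arc
        m = len(poly)
        x, y = poly.marked_indices
        verts = np.roll(poly.vertices, -x, axis=0)
        new_marks = (0, (y - x) % m)
        rolled = ClosedPolygon(verts, marked_indices=new_marks)
        # now mark the complementary pair of vertices instead
        comp = ClosedPolygon(verts, marked_indices=((y - x) % m, m - 1))
        full = classify_polygon(comp, seed=4)
        assert full.label == "3_1"
        rel = loop_relevance(comp, full, seed=4)
        assert not rel.relevant
        assert rel.excised.label == "3_1"
        assert rel.loop_ring.label == "0_1"

    def test_loop_entangled_with_knot_is_relevant(self):
        """Marks splitting a trefoil so neither sub-ring keeps the knot."""
        poly = parametric_knot("3_1", 120, 0.0, 0)
        full = classify_polygon(poly, seed=0)
        found = None
        for x, y in [(10, 70), (20, 80), (0, 60), (30, 90)]:
            marked = ClosedPolygon(poly.vertices, marked_indices=(x, y))
            rel = loop_relevance(marked, full, seed=0)
            if rel.relevant:
                found = rel
                break
        assert found is not None
        # a relevant loop means the excision changed the topology and the
        # knot was not simply localized in the loop
        assert not (
            found.loop_ring.label == "3_1" and found.excised.label == "0_1"
        )

    def test_unknotted_input_rejected(self):
        poly = ClosedPolygon(
            parametric_knot("0_1", 30, 0.0, 0).vertices, marked_indices=(5, 20)
        )
        with pytest.raises(ValueError):
            loop_relevance(poly, KnotType("0_1", 1, 1))

    def test_missing_marks_rejected(self):
        poly = parametric_knot("3_1", 100, 0.0, 0)
        with pytest.raises(ValueError):
            loop_relevance(poly, KnotType("3_1", 3, 7))
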