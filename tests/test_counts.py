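import math

import numpy as np
import pytest

from digraphlets import (
    DirectedNetwork,
    EdgeType,
    degree_counts,
    normalized_signature,
    oracle_signature,
    read_signature_matrix,
    signature_matrix,
    signature_vector,
    triangle_class_counts,
    typed_triangle_counts,
    typed_wedge_counts,
    wedge_class_counts,
    write_signature_matrix,
)
from digraphlets.counts import SIGNATURE_COLUMNS
from digraphlets.oracle import TRIANGLE_CLASSES, WEDGE_CLASSES

from conftest import make_random

OUT, IN, REC = EdgeType.OUT, EdgeType.IN, EdgeType.REC


class TestDegrees:
    def test_out_star_centre(self, out_star3):
        assert degree_counts(out_star3, "c") == (3, 0, 0)

    def test_reciprocal_triangle_vertex(self, reciprocal_triangle):
        assert degree_counts(reciprocal_triangle, "a") == (0, 0, 2)

    def test_matches_neighbor_set_sizes(self):
        g = make_random(12, 0.4, 0.4, seed=21)
        for i in range(g.n):
            out, inn, rec = g.neighbor_sets(i)
            assert degree_counts(g, i) == (len(out), len(inn), len(rec))


class TestTypedWedges:
    def test_path_midpoint(self, path_abc):
        w = typed_wedge_counts(path_abc, "b")
        assert w[(OUT, IN)] == w[(IN, OUT)] == 1
        assert sum(w.values()) == 2

    def test_directed_cycle_has_no_induced_wedges(self, cycle3):
        for v in "abc":
            assert sum(typed_wedge_counts(cycle3, v).values()) == 0

    def test_symmetry_in_type_pair(self):
        g = make_random(10, 0.5, 0.3, seed=4)
        for i in range(g.n):
            w = typed_wedge_counts(g, i)
            for a in (OUT, IN, REC):
                for b in (OUT, IN, REC):
                    assert w[(a, b)] == w[(b, a)]


class TestTypedTriangles:
    def test_paper_example_orientation(self):
        """Triangle {i->h, h->j, i<->j} is a (+, -, rec) triangle at i."""
        g = DirectedNetwork.from_arcs_labelled(
            [("i", "h"), ("h", "j"), ("i", "j"), ("j", "i")]
        )
        t = typed_triangle_counts(g, "i")
        assert t[(OUT, IN, REC)] == 1
        assert sum(t.values()) == 2  # the same triangle under (h, j) swap

    def test_all_reciprocal_triangle(self, reciprocal_triangle):
        t = typed_triangle_counts(reciprocal_triangle, "a")
        assert t[(REC, REC, REC)] == 2
        assert sum(v for k, v in t.items() if k != (REC, REC, REC)) == 0


class TestClassCounts:
    def test_out_star_wedges(self, out_star3):
        w = wedge_class_counts(out_star3, "c")
        assert w["W_out"] == 3  # C(3, 2)
        assert sum(w.values()) == 3

    def test_wedge_endpoints_are_not_centres(self, path_abc):
        assert sum(wedge_class_counts(path_abc, "a").values()) == 0
        assert wedge_class_counts(path_abc, "b")["W_path"] == 1
        assert sum(wedge_class_counts(path_abc, "c").values()) == 0

    @pytest.mark.parametrize(
        "fixture, klass",
        [
            ("reciprocal_triangle", "T_rec"),
            ("cycle3", "T_cycle"),
            ("transitive_triangle", "T_acyclic"),
        ],
    )
    def test_triangle_classes_on_canonical_triangles(self, fixture, klass, request):
        g = request.getfixturevalue(fixture)
        for v in "abc":
            t = triangle_class_counts(g, v)
            assert t[klass] == 1
            assert sum(t.values()) == 1


class TestSignature:
    def test_isolated_vertex_all_zero(self):
        g = DirectedNetwork(["a", "b", "c"], [(1, 2)])
        assert not signature_vector(g, "a").any()

    def test_reciprocal_triangle_signature(self, reciprocal_triangle):
        expected = [0, 0, 2] + [0] * 6 + [0] * 6 + [1]
        assert signature_vector(reciprocal_triangle, "a").tolist() == expected

    def test_column_order(self, reciprocal_triangle):
        s = signature_matrix(reciprocal_triangle)
        assert tuple(s.columns) == SIGNATURE_COLUMNS
        assert list(s.index) == list(reciprocal_triangle.labels)

    def test_matches_oracle_row_for_row(self):
        g = make_random(12, 0.5, 0.4, seed=42)
        s = signature_matrix(g).to_numpy()
        for i, lab in enumerate(g.labels):
            assert np.array_equal(s[i], oracle_signature(g, lab)), lab

    def test_round_trip_tsv(self, tmp_path, reciprocal_triangle):
        s = signature_matrix(reciprocal_triangle)
        p = tmp_path / "sig.tsv"
        write_signature_matrix(s, p, comments=["test"])
        assert read_signature_matrix(p).equals(s)


class TestConservation:
    """Global identities tying per-vertex counts to network totals."""

    def test_degree_totals(self, random_graphs):
        for g in random_graphs:
            s = signature_matrix(g)
            assert s["d_out"].sum() == s["d_in"].sum() == g.n_pure_arcs
            assert s["d_rec"].sum() == 2 * g.n_reciprocal_dyads

    def test_wedge_and_triangle_totals(self, random_graphs):
        """Each wedge has one centre; each triangle three incident vertices."""
        import itertools

        from digraphlets.oracle import classify_triangle, classify_wedge_center

        for g in random_graphs:
            s = signature_matrix(g)
            wedge_totals = {c: 0 for c in WEDGE_CLASSES}
            tri_totals = {c: 0 for c in TRIANGLE_CLASSES}
            arcs = set(g.arcs)
            for tri in itertools.combinations(range(g.n), 3):
                types = {
                    (u, v): g.edge_type(u, v)
                    for u, v in itertools.combinations(tri, 2)
                }
                adj = [p for p, t in types.items() if t is not None]
                if len(adj) == 3:
                    tri_totals[classify_triangle(arcs, tri)] += 1
                elif len(adj) == 2:
                    (centre,) = set(adj[0]) & set(adj[1])
                    t1 = g.edge_type(centre, next(x for x in adj[0] if x != centre))
                    t2 = g.edge_type(centre, next(x for x in adj[1] if x != centre))
                    wedge_totals[classify_wedge_center(t1, t2)] += 1
            for c in WEDGE_CLASSES:
                assert s[c].sum() == wedge_totals[c], c
            for c in TRIANGLE_CLASSES:
                assert s[c].sum() == 3 * tri_totals[c], c

    def test_complete_reciprocal_graph(self):
        """K_n of reciprocal dyads: no induced wedges; T_rec = C(n-1, 2)."""
        n = 7
        arcs = [(i, j) for i in range(n) for j in range(n) if i != j]
        g = DirectedNetwork([f"v{k}" for k in range(n)], arcs)
        s = signature_matrix(g)
        assert s[list(WEDGE_CLASSES)].to_numpy().sum() == 0
        assert (s["T_rec"] == math.comb(n - 1, 2)).all()
        assert s[[c for c in TRIANGLE_CLASSES if c != "T_rec"]].to_numpy().sum() == 0


class TestNormalizedSignature:
    def test_degree_block(self):
        f = np.zeros(16)
        f[:3] = [2, 1, 1]
        norm, degenerate = normalized_signature(f)
        assert norm[:3].tolist() == [0.5, 0.25, 0.25]
        assert degenerate == ["wedges", "triangles"]

    def test_all_zero_flagged(self):
        norm, degenerate = normalized_signature(np.zeros(16))
        assert not norm.any()
        assert degenerate == ["degrees", "wedges", "triangles"]

    def test_blocks_sum_to_one(self, reciprocal_triangle):
        norm, degenerate = normalized_signature(
            signature_vector(reciprocal_triangle, "a")
        )
        assert norm[:3].sum() == pytest.approx(1)
        assert norm[9:].sum() == pytest.approx(1)
        assert degenerate == ["wedges"]
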