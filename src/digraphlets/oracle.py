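"""Brute-force reference counting and exhaustive class enumeration.

Everything here is deliberately slow and simple: induced subgraphs on all
vertex pairs/triples are classified one by one, and isomorphism classes of
small directed graphs are found by minimising an encoding over all vertex
permutations.  The fast matrix-product counters are pinned to this module in
the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .network import DirectedNetwork, EdgeType, NetworkError

__all__ = [
    "canonical_form",
    "oracle_signature",
    "enumerate_connected_digraphs",
    "enumerate_typed_labels",
    "classify_triangle",
    "classify_wedge_center",
    "WEDGE_CLASSES",
    "TRIANGLE_CLASSES",
]

#: Canonical order of the 6 wedge classes (wedge centred at the vertex).
WEDGE_CLASSES = ("W_out", "W_in", "W_path", "W_out_rec", "W_in_rec", "W_rec")

#: Canonical order of the 7 triangle classes.
TRIANGLE_CLASSES = (
    "T_acyclic",
    "T_cycle",
    "T_out_rec",
    "T_in_rec",
    "T_cycle_rec",
    "T_cycle_rec2",
    "T_rec",
)

# Pair states: 0 absent, 1 forward (u -> v), 2 backward (v -> u), 3 reciprocal.
_ABSENT, _FWD, _BWD, _REC = 0, 1, 2, 3


def _pair_state(arcs: set[tuple[int, int]], u: int, v: int) -> int:
    fwd, bwd = (u, v) in arcs, (v, u) in arcs
    return (_REC if bwd else _FWD) if fwd else (_BWD if bwd else _ABSENT)


def _state_matrix(states: dict[tuple[int, int], int], k: int) -> dict:
    """Normalize so keys are (u, v) with u < v."""
    out = {}
    for (u, v), s in states.items():
        if u > v:
            u, v = v, u
            s = {_FWD: _BWD, _BWD: _FWD}.get(s, s)
        out[(u, v)] = s
    return out


def canonical_form(states: dict[tuple[int, int], int], k: int) -> tuple[int, ...]:
    """Canonical label of a k-node directed graph (k <= 3): the minimum,
    over all k! vertex permutations, of the tuple of pair states read in
    lexicographic pair order."""
    states = _state_matrix(states, k)
    pairs = list(itertools.combinations(range(k), 2))
    best = None
    for perm in itertools.permutations(range(k)):
        enc = []
        for u, v in pairs:
            pu, pv = perm[u], perm[v]
            if pu < pv:
                s = states.get((pu, pv), _ABSENT)
            else:
                s = states.get((pv, pu), _ABSENT)
                s = {_FWD: _BWD, _BWD: _FWD}.get(s, s)
            enc.append(s)
        enc = tuple(enc)
        if best is None or enc < best:
            best = enc
    return best


def _weakly_connected(states: dict[tuple[int, int], int], k: int) -> bool:
    adj = {u: set() for u in range(k)}
    for (u, v), s in states.items():
        if s != _ABSENT:
            adj[u].add(v)
            adj[v].add(u)
    seen, stack = {0}, [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == k


def classify_wedge_center(t1: EdgeType, t2: EdgeType) -> str:
    """Wedge class from the types of the two centre edges (seen from the
    centre); the unordered type pair determines the class."""
    key = frozenset_multiset(t1, t2)
    return {
        (EdgeType.OUT, EdgeType.OUT): "W_out",
        (EdgeType.IN, EdgeType.IN): "W_in",
        (EdgeType.OUT, EdgeType.IN): "W_path",
        (EdgeType.OUT, EdgeType.REC): "W_out_rec",
        (EdgeType.IN, EdgeType.REC): "W_in_rec",
        (EdgeType.REC, EdgeType.REC): "W_rec",
    }[key]


def frozenset_multiset(t1: EdgeType, t2: EdgeType) -> tuple[EdgeType, EdgeType]:
    return (t1, t2) if t1 <= t2 else (t2, t1)


def classify_triangle(arcs: set[tuple[int, int]], tri: tuple[int, int, int]) -> str:
    """Isomorphism class of a triangle (all three pairs adjacent).

    Classes are fixed by the number of reciprocal dyads:

    * 0 dyads: three pure arcs — ``T_cycle`` if they form a directed cycle,
      else ``T_acyclic`` (transitive).
    * 1 dyad: the third vertex sends to both dyad members (``T_out_rec``),
      receives from both (``T_in_rec``), or one of each (``T_cycle_rec``).
    * 2 dyads: ``T_cycle_rec2``;  3 dyads: ``T_rec``.
    """
    a, b, c = tri
    pairs = [(a, b), (a, c), (b, c)]
    dyads = [(u, v) for u, v in pairs if (u, v) in arcs and (v, u) in arcs]
    ndy = len(dyads)
    if ndy == 3:
        return "T_rec"
    if ndy == 2:
        return "T_cycle_rec2"
    if ndy == 1:
        u, v = dyads[0]
        (w,) = set(tri) - {u, v}
        to_u, to_v = (w, u) in arcs, (w, v) in arcs
        if to_u and to_v:
            return "T_out_rec"
        if not to_u and not to_v:
            return "T_in_rec"
        return "T_cycle_rec"
    # no dyads: directed cycle iff out-degrees within the triangle are all 1
    outdeg = {x: sum(((x, y) in arcs) for y in tri if y != x) for x in tri}
    return "T_cycle" if all(d == 1 for d in outdeg.values()) else "T_acyclic"


def oracle_signature(
    g: DirectedNetwork, vertex, max_n: int = 50
) -> np.ndarray:
    """16-dim signature of a vertex by exhaustive pair enumeration.

    Enumerates every unordered pair {h, j} of other vertices and classifies
    the induced subgraph on {i, h, j}: a wedge contributes only when i is
    its centre; a triangle contributes whatever position i holds.
    """
    if g.n > max_n:
        raise NetworkError(
            f"oracle refuses n={g.n} > cap {max_n}; use the fast path"
        )
    i = g.index(vertex)
    arcs = set(g.arcs)
    out, inn, rec = g.neighbor_sets(i)
    deg = np.array([len(out), len(inn), len(rec)], dtype=np.int64)

    wedge = {c: 0 for c in WEDGE_CLASSES}
    tri = {c: 0 for c in TRIANGLE_CLASSES}
    others = [v for v in range(g.n) if v != i]
    for h, j in itertools.combinations(others, 2):
        t_ih = g.edge_type(i, h)
        t_ij = g.edge_type(i, j)
        t_hj = g.edge_type(h, j)
        n_adj = sum(t is not None for t in (t_ih, t_ij, t_hj))
        if n_adj == 3:
            tri[classify_triangle(arcs, (i, h, j))] += 1
        elif n_adj == 2 and t_ih is not None and t_ij is not None:
            # induced wedge centred at i
            wedge[classify_wedge_center(t_ih, t_ij)] += 1
    return np.concatenate(
        [
            deg,
            [wedge[c] for c in WEDGE_CLASSES],
            [tri[c] for c in TRIANGLE_CLASSES],
        ]
    ).astype(np.int64)


@dataclass(frozen=True)
class ClassEnumeration:
    """Distinct isomorphism classes of weakly connected k-node digraphs."""

    k: int
    classes: tuple[tuple[int, ...], ...]
    wedge_classes: tuple[tuple[int, ...], ...]  # exactly 2 adjacent pairs
    triangle_classes: tuple[tuple[int, ...], ...]  # all 3 pairs adjacent


def enumerate_connected_digraphs(k: int) -> ClassEnumeration:
    """Enumerate isomorphism classes of weakly connected digraphs on k nodes
    (k = 2 or 3) by exhausting all pair-state assignments and reducing under
    vertex permutations."""
    if k not in (2, 3):
        raise ValueError(f"unsupported k={k}; only 2 and 3 are enumerable here")
    pairs = list(itertools.combinations(range(k), 2))
    seen: dict[tuple[int, ...], int] = {}  # canonical form -> n adjacent pairs
    for assignment in itertools.product(range(4), repeat=len(pairs)):
        states = dict(zip(pairs, assignment))
        if not _weakly_connected(states, k):
            continue
        cf = canonical_form(states, k)
        seen[cf] = sum(s != _ABSENT for s in assignment)
    classes = tuple(sorted(seen))
    wedges = tuple(c for c in classes if k == 3 and seen[c] == 2)
    triangles = tuple(c for c in classes if k == 3 and seen[c] == 3)
    return ClassEnumeration(
        k=k, classes=classes, wedge_classes=wedges, triangle_classes=triangles
    )


def enumerate_typed_labels() -> dict[str, int]:
    """Totals of ordered typed labels and class-reduced dimensions.

    Three edge types give 3 degree types, 3^2 = 9 ordered wedge types and
    3^3 = 27 ordered triangle types (39 per-vertex typed quantities); class
    reduction gives 3 + 6 + 7 = 16 signature coordinates.
    """
    types = len(EdgeType)
    e3 = enumerate_connected_digraphs(3)
    counts = {
        "degree_types": types,
        "wedge_types": types**2,
        "triangle_types": types**3,
        "wedge_classes": len(e3.wedge_classes),
        "triangle_classes": len(e3.triangle_classes),
    }
    counts["typed_quantities"] = (
        counts["degree_types"] + counts["wedge_types"] + counts["triangle_types"]
    )
    counts["signature_dimension"] = (
        counts["degree_types"]
        + counts["wedge_classes"]
        + counts["triangle_classes"]
    )
    return counts
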