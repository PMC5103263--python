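"""Fast 2-/3-node directed graphlet counting and signature matrices.

Per vertex ``i`` the counters produce

* three degrees ``d+, d-, do`` — sizes of the out-only, in-only and
  reciprocal neighbour sets;
* nine typed wedge counts ``W_i(a, b)`` — ordered pairs ``(h, j)`` with
  ``h`` an ``a``-neighbour and ``j`` a ``b``-neighbour of ``i`` and the
  ``h–j`` pair **non-adjacent** (only induced wedges are graphlets);
* twenty-seven typed triangle counts ``T_i(a, b, c)`` — over ``c``-neighbours
  ``j`` of ``i``, the number of common ``a``-neighbours of ``i`` and
  ``b``-neighbours of ``j``.

Typed counts reduce to 6 wedge and 7 triangle isomorphism classes; together
with the degrees this yields the 16-dimensional signature vector
``[d+, d-, do, W..., T...]``.  All class counts are counts of *distinct*
subgraphs: each wedge is counted once (at its centre) and each triangle once
per incident vertex, so the typed sums are halved (each unordered neighbour
pair appears twice as an ordered pair).

Everything is computed with dense typed-adjacency matrix products, O(n^3);
correctness is pinned to the exhaustive oracle in the tests.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd

from .network import DirectedNetwork, EdgeType
from .oracle import (
    TRIANGLE_CLASSES,
    WEDGE_CLASSES,
    classify_triangle,
    classify_wedge_center,
)

__all__ = [
    "SIGNATURE_COLUMNS",
    "degree_counts",
    "typed_wedge_counts",
    "typed_triangle_counts",
    "wedge_class_counts",
    "triangle_class_counts",
    "signature_vector",
    "signature_matrix",
    "normalized_signature",
    "write_signature_matrix",
    "read_signature_matrix",
]

#: Fixed column order of the 16-dimensional signature.
SIGNATURE_COLUMNS = ("d_out", "d_in", "d_rec") + WEDGE_CLASSES + TRIANGLE_CLASSES

_TYPES = (EdgeType.OUT, EdgeType.IN, EdgeType.REC)


# -- typed counts, vectorized over all vertices ------------------------------


def _degree_table(g: DirectedNetwork) -> np.ndarray:
    """(n, 3) degrees per type; row sums of the typed adjacency matrices."""
    ta = g.typed_adjacency()
    return np.stack(
        [ta.by_type(t).sum(axis=1, dtype=np.int64) for t in _TYPES], axis=1
    )

def _typed_wedge_table(g: DirectedNetwork) -> np.ndarray:
    """(n, 3, 3) induced typed wedge counts W_i(a, b) for all vertices.

    Raw ordered pairs minus pairs closed by an h–j edge of either direction.
    """
    ta = g.typed_adjacency()
    u = ta.skeleton.astype(np.int64)
    mats = [ta.by_type(t).astype(np.int64) for t in _TYPES]
    deg = _degree_table(g)
    n = g.n
    w = np.zeros((n, 3, 3), dtype=np.int64)
    for a, aa in enumerate(mats):
        au = aa @ u
        for b, ab in enumerate(mats):
            raw = deg[:, a] * deg[:, b] - (deg[:, a] if a == b else 0)
            closed = np.einsum("ij,ij->i", au, ab)
            w[:, a, b] = raw - closed
    return w


def _typed_triangle_table(g: DirectedNetwork) -> np.ndarray:
    """(n, 3, 3, 3) typed triangle counts T_i(a, b, c).

    T_i(a, b, c) = sum over c-neighbours j of i of the number of common
    a-neighbours of i and b-neighbours of j; the h–j edge is typed with
    respect to j, hence the A_b transpose in the product.
    """
    ta = g.typed_adjacency()
    mats = [ta.by_type(t).astype(np.int64) for t in _TYPES]
    n = g.n
    t = np.zeros((n, 3, 3, 3), dtype=np.int64)
    for a, b in itertools.product(range(3), repeat=2):
        common = mats[a] @ mats[b].T  # (i, j) -> |N_a(i) ∩ N_b(j)|
        for c in range(3):
            t[:, a, b, c] = np.einsum("ij,ij->i", common, mats[c])
    return t


# -- typed -> class reduction -------------------------------------------------


@lru_cache(maxsize=1)
def _wedge_class_map() -> np.ndarray:
    """(3, 3) array mapping the ordered type pair (a, b) of a wedge's two
    centre edges to its class index in WEDGE_CLASSES."""
    m = np.empty((3, 3), dtype=np.int64)
    for a, b in itertools.product(_TYPES, repeat=2):
        m[int(a), int(b)] = WEDGE_CLASSES.index(classify_wedge_center(a, b))
    return m


@lru_cache(maxsize=1)
def _triangle_class_map() -> np.ndarray:
    """(3, 3, 3) array mapping the typed label (a, b, c) of a triangle to its
    isomorphism class index in TRIANGLE_CLASSES.

    The label is decoded back into a concrete 3-node digraph on {i, h, j}:
    the i–h edge has type a and the i–j edge type c seen from i, the h–j
    edge type b seen from j; the whole triangle is then classified
    structurally, so the reduction is consistent with subgraph isomorphism
    by construction.
    """
    i, h, j = 0, 1, 2

    def arcs_for(u: int, v: int, t: EdgeType) -> set[tuple[int, int]]:
        # type seen from u: OUT u->v, IN v->u, REC both
        if t == EdgeType.OUT:
            return {(u, v)}
        if t == EdgeType.IN:
            return {(v, u)}
        return {(u, v), (v, u)}

    m = np.empty((3, 3, 3), dtype=np.int64)
    for a, b, c in itertools.product(_TYPES, repeat=3):
        arcs = arcs_for(i, h, a) | arcs_for(i, j, c) | arcs_for(j, h, b)
        m[int(a), int(b), int(c)] = TRIANGLE_CLASSES.index(
            classify_triangle(arcs, (i, h, j))
        )
    return m


def _reduce_classes(w_typed: np.ndarray, t_typed: np.ndarray) -> np.ndarray:
    """Reduce per-vertex typed counts to the 13 class counts.

    Every distinct wedge centred at i appears exactly twice across the 9
    ordered typed counts (the two orderings of its endpoints), and every
    distinct triangle through i exactly twice across the 27 typed counts,
    so class totals are the typed sums halved.
    """
    n = w_typed.shape[0]
    wm, tm = _wedge_class_map(), _triangle_class_map()
    wsum = np.zeros((n, len(WEDGE_CLASSES)), dtype=np.int64)
    for a, b in itertools.product(range(3), repeat=2):
        wsum[:, wm[a, b]] += w_typed[:, a, b]
    tsum = np.zeros((n, len(TRIANGLE_CLASSES)), dtype=np.int64)
    for a, b, c in itertools.product(range(3), repeat=3):
        tsum[:, tm[a, b, c]] += t_typed[:, a, b, c]
    if np.any(wsum % 2) or np.any(tsum % 2):
        raise AssertionError("odd typed-class sum; counting invariant violated")
    return np.concatenate([wsum // 2, tsum // 2], axis=1)


# -- public per-vertex / per-network API --------------------------------------


def degree_counts(g: DirectedNetwork, vertex) -> tuple[int, int, int]:
    """(d+, d-, do): out-, in- and reciprocal-degree of a vertex."""
    i = g.index(vertex)
    return tuple(int(x) for x in _degree_table(g)[i])


def typed_wedge_counts(g: DirectedNetwork, vertex) -> dict[tuple[EdgeType, EdgeType], int]:
    """The 9 induced typed wedge counts W_i(a, b) of a vertex."""
    i = g.index(vertex)
    w = _typed_wedge_table(g)[i]
    return {
        (a, b): int(w[int(a), int(b)]) for a, b in itertools.product(_TYPES, repeat=2)
    }


def typed_triangle_counts(
    g: DirectedNetwork, vertex
) -> dict[tuple[EdgeType, EdgeType, EdgeType], int]:
    """The 27 typed triangle counts T_i(a, b, c) of a vertex."""
    i = g.index(vertex)
    t = _typed_triangle_table(g)[i]
    return {
        (a, b, c): int(t[int(a), int(b), int(c)])
        for a, b, c in itertools.product(_TYPES, repeat=3)
    }


def wedge_class_counts(g: DirectedNetwork, vertex) -> dict[str, int]:
    """Distinct induced wedges centred at the vertex, per class."""
    i = g.index(vertex)
    row = _reduce_classes(_typed_wedge_table(g), _typed_triangle_table(g))[i]
    return dict(zip(WEDGE_CLASSES, (int(x) for x in row[: len(WEDGE_CLASSES)])))


def triangle_class_counts(g: DirectedNetwork, vertex) -> dict[str, int]:
    """Distinct triangles through the vertex (any position), per class."""
    i = g.index(vertex)
    row = _reduce_classes(_typed_wedge_table(g), _typed_triangle_table(g))[i]
    return dict(
        zip(TRIANGLE_CLASSES, (int(x) for x in row[len(WEDGE_CLASSES):]))
    )


def signature_array(g: DirectedNetwork) -> np.ndarray:
    """(n, 16) integer signature array in label order (no pandas overhead)."""
    deg = _degree_table(g)
    classes = _reduce_classes(_typed_wedge_table(g), _typed_triangle_table(g))
    return np.concatenate([deg, classes], axis=1)


def signature_matrix(g: DirectedNetwork) -> pd.DataFrame:
    """N x 16 signature matrix; rows follow the network's label order."""
    return pd.DataFrame(
        signature_array(g), index=list(g.labels), columns=list(SIGNATURE_COLUMNS)
    )


def signature_vector(g: DirectedNetwork, vertex) -> np.ndarray:
    """16-dim signature [d+, d-, do | 6 wedge classes | 7 triangle classes]."""
    i = g.index(vertex)
    return signature_matrix(g).to_numpy()[i]


def normalized_signature(f: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Blockwise-normalised signature (degrees, wedges, triangles sum to 1
    within each block).  A zero-sum block maps to zeros and is reported in
    the returned list of degenerate block names."""
    f = np.asarray(f, dtype=float)
    if f.shape != (16,):
        raise ValueError("signature vector must have 16 entries")
    out = np.zeros(16)
    degenerate = []
    for name, sl in (("degrees", slice(0, 3)), ("wedges", slice(3, 9)),
                     ("triangles", slice(9, 16))):
        s = f[sl].sum()
        if s > 0:
            out[sl] = f[sl] / s
        else:
            degenerate.append(name)
    return out, degenerate


# -- I/O ----------------------------------------------------------------------


def write_signature_matrix(s: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    """Write a signature matrix as TSV (label column + 16 named columns)."""
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        s.to_csv(fh, sep="\t", index_label="vertex")


def read_signature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    missing = set(SIGNATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"signature file missing columns: {sorted(missing)}")
    return df[list(SIGNATURE_COLUMNS)]
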