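"""Simple directed networks with out/in/reciprocal edge typing.

A :class:`DirectedNetwork` is a simple directed graph (no self-arcs, no
duplicate arcs).  A pair of opposite arcs ``{(i, j), (j, i)}`` is treated as a
single *reciprocal* dyad; every ordered adjacent pair therefore has exactly
one of three types:

* ``OUT`` — ``i -> j`` present, ``j -> i`` absent (type ``+`` seen from ``i``)
* ``IN``  — ``j -> i`` present, ``i -> j`` absent (type ``-`` seen from ``i``)
* ``REC`` — both present (type ``o``)

The typed indicator matrices ``A+``, ``A-``, ``Ao`` partition the adjacency
structure: ``A-`` is the transpose of ``A+``, ``Ao`` is symmetric, and at most
one of the three is 1 for any ordered pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EdgeType",
    "DirectedNetwork",
    "TypedAdjacency",
    "read_edge_list",
    "read_adjacency",
    "write_network",
]


class EdgeType(enum.IntEnum):
    """Type of an adjacent ordered pair, seen from its first vertex."""

    OUT = 0  # "+"
    IN = 1  # "-"
    REC = 2  # "o"

    @property
    def symbol(self) -> str:
        return "+-o"[int(self)]


class NetworkError(ValueError):
    """Invalid network construction or lookup."""


class ParseError(NetworkError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class TypedAdjacency:
    """Binary indicator matrices for out-, in- and reciprocal edges."""

    a_out: np.ndarray
    a_in: np.ndarray
    a_rec: np.ndarray

    def by_type(self, t: EdgeType) -> np.ndarray:
        return (self.a_out, self.a_in, self.a_rec)[int(t)]

    @property
    def skeleton(self) -> np.ndarray:
        """Symmetric 0/1 matrix of connected (adjacent) pairs."""
        return self.a_out | self.a_in | self.a_rec


class DirectedNetwork:
    """Simple directed graph over labelled vertices.

    Parameters
    ----------
    labels
        Ordered vertex identifiers (strings); fixes the index order used by
        every matrix the package produces.
    arcs
        Ordered index pairs ``(i, j)``, ``i != j``.  Opposite pairs may both
        be present; together they form one reciprocal dyad.
    weights
        Optional mapping from arcs to real weights, preserved for
        preprocessing; binary analyses ignore it.
    """

    def __init__(
        self,
        labels: Sequence[str],
        arcs: Iterable[tuple[int, int]],
        weights: Mapping[tuple[int, int], float] | None = None,
    ):
        labels = tuple(str(x) for x in labels)
        if len(set(labels)) != len(labels):
            raise NetworkError("duplicate vertex labels")
        arcset = set()
        for i, j in arcs:
            if i == j:
                raise NetworkError(f"self-arc on vertex {labels[i]!r}")
            if not (0 <= i < len(labels) and 0 <= j < len(labels)):
                raise NetworkError(f"arc ({i}, {j}) out of range")
            arcset.add((int(i), int(j)))
        self._labels = labels
        self._arcs = frozenset(arcset)
        self._index = {lab: k for k, lab in enumerate(labels)}
        self.weights = dict(weights) if weights else None

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self._labels)

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def arcs(self) -> frozenset[tuple[int, int]]:
        return self._arcs

    def index(self, label_or_index) -> int:
        if isinstance(label_or_index, (int, np.integer)):
            i = int(label_or_index)
            if not 0 <= i < self.n:
                raise NetworkError(f"vertex index {i} out of range")
            return i
        try:
            return self._index[str(label_or_index)]
        except KeyError:
            raise NetworkError(f"unknown vertex {label_or_index!r}") from None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DirectedNetwork)
            and self._labels == other._labels
            and self._arcs == other._arcs
        )

    def __repr__(self) -> str:
        return (
            f"DirectedNetwork(n={self.n}, pure_arcs={self.n_pure_arcs}, "
            f"reciprocal_dyads={self.n_reciprocal_dyads})"
        )

    # -- edge typing -------------------------------------------------------

    @property
    def n_pure_arcs(self) -> int:
        return sum(1 for (i, j) in self._arcs if (j, i) not in self._arcs)

    @property
    def n_reciprocal_dyads(self) -> int:
        return sum(1 for (i, j) in self._arcs if (j, i) in self._arcs) // 2

    def adjacency(self) -> np.ndarray:
        """Plain 0/1 adjacency; entry (i, j) = 1 iff arc i -> j exists."""
        a = np.zeros((self.n, self.n), dtype=np.uint8)
        for i, j in self._arcs:
            a[i, j] = 1
        return a

    def typed_adjacency(self) -> TypedAdjacency:
        a = self.adjacency()
        rec = a & a.T
        out = a & ~rec & 1
        return TypedAdjacency(a_out=out, a_in=out.T.copy(), a_rec=rec)

    def neighbor_sets(self, vertex) -> tuple[set[int], set[int], set[int]]:
        """Return ``(N+, N-, No)`` for a vertex: out-only, in-only and
        reciprocal neighbours.  The three sets are pairwise disjoint."""
        i = self.index(vertex)
        out, inn, rec = set(), set(), set()
        for a, b in self._arcs:
            if a == i:
                (rec if (b, a) in self._arcs else out).add(b)
            elif b == i:
                if (b, a) not in self._arcs:
                    inn.add(a)
        return out, inn, rec

    def edge_type(self, i: int, j: int) -> EdgeType | None:
        """Type of the ordered pair (i, j), or None when not adjacent."""
        fwd, bwd = (i, j) in self._arcs, (j, i) in self._arcs
        if fwd and bwd:
            return EdgeType.REC
        if fwd:
            return EdgeType.OUT
        if bwd:
            return EdgeType.IN
        return None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_arcs_labelled(
        cls,
        pairs: Iterable[tuple[str, str]],
        labels: Sequence[str] | None = None,
        weights: Mapping[tuple[str, str], float] | None = None,
    ) -> "DirectedNetwork":
        """Build from labelled arcs; labels default to order of appearance."""
        pairs = list(pairs)
        if labels is None:
            seen: dict[str, None] = {}
            for s, t in pairs:
                seen.setdefault(str(s))
                seen.setdefault(str(t))
            labels = list(seen)
        idx = {str(lab): k for k, lab in enumerate(labels)}
        arcs = [(idx[str(s)], idx[str(t)]) for s, t in pairs]
        w = None
        if weights:
            w = {(idx[str(s)], idx[str(t)]): v for (s, t), v in weights.items()}
        return cls(labels, arcs, weights=w)

    @classmethod
    def from_adjacency(
        cls, a: np.ndarray, labels: Sequence[str] | None = None
    ) -> "DirectedNetwork":
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkError("adjacency matrix must be square")
        if np.any(np.diagonal(a) != 0):
            raise NetworkError("self-arcs are excluded (nonzero diagonal)")
        n = a.shape[0]
        if labels is None:
            labels = [f"v{k}" for k in range(n)]
        ii, jj = np.nonzero(a)
        return cls(labels, zip(ii.tolist(), jj.tolist()))


# -- I/O --------------------------------------------------------------------

_VERTICES_TAG = "# vertices:"


def read_edge_list(path) -> DirectedNetwork:
    """Read a TSV edge list: ``source<TAB>target[<TAB>weight]`` per line.

    ``#``-prefixed comment lines are allowed; a ``# vertices:`` header fixes
    the full label set (required to round-trip isolated vertices).  Opposite
    records form one reciprocal dyad; duplicates are collapsed.
    """
    pairs: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}
    header_labels: list[str] | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith(_VERTICES_TAG):
                header_labels = line[len(_VERTICES_TAG):].split()
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"expected 2 or 3 tab-separated fields, got {len(parts)}", ln
                )
            s, t = parts[0].strip(), parts[1].strip()
            if not s or not t:
                raise ParseError("empty vertex label", ln)
            if s == t:
                raise ParseError(f"self-arc on vertex {s!r} is not allowed", ln)
            if len(parts) == 3:
                try:
                    weights[(s, t)] = float(parts[2])
                except ValueError:
                    raise ParseError(f"bad weight {parts[2]!r}", ln) from None
            pairs.append((s, t))
    return DirectedNetwork.from_arcs_labelled(
        pairs, labels=header_labels, weights=weights or None
    )


def read_adjacency(path) -> DirectedNetwork:
    """Read a dense 0/1 adjacency CSV (header row + first column = labels)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0, comment=None)
    labels = [str(c) for c in df.columns]
    if [str(r) for r in df.index] != labels:
        raise ParseError("adjacency CSV row labels must match column labels")
    return DirectedNetwork.from_adjacency(df.to_numpy(), labels)


def write_network(g: DirectedNetwork, path, fmt: str = "edge-list") -> None:
    """Write a network; ``fmt`` is ``edge-list`` (TSV) or ``adjacency`` (CSV).

    Reciprocal dyads are serialized as both ordered records so the file is
    lossless and tool-agnostic; ``read(write(g))`` reproduces ``g``.
    """
    path = Path(path)
    if fmt == "edge-list":
        lines = [f"{_VERTICES_TAG} " + " ".join(g.labels)]
        for i, j in sorted(g.arcs):
            if g.weights and (i, j) in g.weights:
                lines.append(f"{g.labels[i]}\t{g.labels[j]}\t{g.weights[i, j]!r}")
            else:
                lines.append(f"{g.labels[i]}\t{g.labels[j]}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "adjacency":
        import pandas as pd

        pd.DataFrame(g.adjacency(), index=g.labels, columns=g.labels).to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
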