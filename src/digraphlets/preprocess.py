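"""Sign splitting and density pruning of signed weighted connectivity.

Effective-connectivity estimators (e.g. Granger-causality path coefficients)
produce dense signed weight matrices: positive entries are excitatory causal
effects, negative entries inhibitory.  The pipeline splits a matrix by sign
into an excitatory and an inhibitory nonnegative weight matrix, then prunes
each to the smallest proportion of strongest weights such that

(i)  at least ``connect_fraction`` of the vertices lie in the largest weakly
     connected component (default 99%), and
(ii) every vertex inside that component has undirected degree (number of
     distinct neighbours) of at least ``degree_factor * ln(N)`` (default 2).

Retention is monotone — adding arcs can only grow the component and the
degrees — so the minimal retained-arc count is found by binary search and
verified post hoc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import DirectedNetwork, NetworkError

__all__ = [
    "SignedWeightedNetwork",
    "PruneResult",
    "PruningInfeasibleError",
    "split_by_sign",
    "prune",
    "read_weight_matrix",
    "write_weight_matrix",
]


@dataclass(frozen=True)
class SignedWeightedNetwork:
    """Dense n x n signed weight matrix with zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkError("weight matrix must be square")
        if w.shape[0] != len(self.labels):
            raise NetworkError("label count does not match matrix size")
        if not np.all(np.isfinite(w)):
            raise NetworkError("weights must be finite")
        if np.any(np.diagonal(w) != 0):
            raise NetworkError("diagonal must be exactly zero (no self-effects)")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)


def split_by_sign(
    wm: SignedWeightedNetwork,
) -> tuple[SignedWeightedNetwork, SignedWeightedNetwork]:
    """Split into (excitatory, inhibitory) nonnegative weight matrices:
    the excitatory keeps positive entries, the inhibitory keeps the
    magnitudes of negative entries."""
    w = wm.weights
    exc = np.where(w > 0, w, 0.0)
    inh = np.where(w < 0, -w, 0.0)
    return (
        SignedWeightedNetwork(exc, wm.labels),
        SignedWeightedNetwork(inh, wm.labels),
    )


class PruningInfeasibleError(ValueError):
    """No retention proportion satisfies both pruning criteria; carries the
    best achievable criteria values at full retention."""

    def __init__(self, message: str, best: dict):
        self.best = best
        super().__init__(f"{message}; best achievable: {best}")


@dataclass(frozen=True)
class PruneResult:
    """Pruned binary network plus the chosen retention proportion."""

    network: DirectedNetwork
    proportion: float  # retained fraction of nonzero entries
    n_arcs: int
    criteria: dict


def _skeleton_stats(arcs: Sequence[tuple[int, int]], n: int) -> tuple[np.ndarray, int, int]:
    """(component labels of largest weak component as bool mask, its size,
    min skeleton degree inside it)."""
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in arcs:
        adj[i].add(j)
        adj[j].add(i)
    seen = np.full(n, -1)
    comp_sizes = []
    for start in range(n):
        if seen[start] >= 0:
            continue
        cid = len(comp_sizes)
        stack, members = [start], [start]
        seen[start] = cid
        while stack:
            for w in adj[stack.pop()]:
                if seen[w] < 0:
                    seen[w] = cid
                    stack.append(w)
                    members.append(w)
        comp_sizes.append(len(members))
    largest = int(np.argmax(comp_sizes))
    mask = seen == largest
    mindeg = min(len(adj[v]) for v in range(n) if mask[v])
    return mask, int(comp_sizes[largest]), int(mindeg)


def prune(
    wm: SignedWeightedNetwork,
    connect_fraction: float = 0.99,
    degree_factor: float = 2.0,
) -> PruneResult:
    """Binarise by keeping the minimal proportion of strongest weights that
    satisfies the connectivity and minimum-degree criteria.

    Entries are ranked by descending magnitude (ties broken by row, then
    column index, for determinism); the retained top-k entries become arcs.
    Vertices outside the largest weak component (at most
    ``1 - connect_fraction`` of them) are exempt from the degree criterion.
    """
    if wm.n < 3:
        raise NetworkError("pruning needs at least 3 vertices")
    if np.any(wm.weights < 0):
        raise NetworkError("prune expects nonnegative weights; split by sign first")
    n = wm.n
    ii, jj = np.nonzero(wm.weights)
    mags = wm.weights[ii, jj]
    order = np.lexsort((jj, ii, -mags))  # magnitude desc, then (row, col)
    ranked = list(zip(ii[order].tolist(), jj[order].tolist()))
    m = len(ranked)
    need_conn = math.ceil(connect_fraction * n)
    need_deg = degree_factor * math.log(n)

    def feasible(k: int) -> tuple[bool, dict]:
        mask, comp, mindeg = _skeleton_stats(ranked[:k], n)
        ok = comp >= need_conn and mindeg >= need_deg
        return ok, {
            "largest_component": comp,
            "required_component": need_conn,
            "min_degree_in_component": mindeg,
            "required_min_degree": need_deg,
        }

    if m == 0 or not feasible(m)[0]:
        _, best = feasible(m) if m else (False, {
            "largest_component": 1, "required_component": need_conn,
            "min_degree_in_component": 0, "required_min_degree": need_deg,
        })
        raise PruningInfeasibleError(
            "no retention proportion satisfies the pruning criteria", best
        )
    lo, hi = 1, m  # invariant: hi feasible
    while lo < hi:
        mid = (lo + hi) // 2
        if feasible(mid)[0]:
            hi = mid
        else:
            lo = mid + 1
    k = hi
    ok, crit = feasible(k)
    assert ok, "binary search returned an infeasible retention level"
    net = DirectedNetwork(wm.labels, ranked[:k])
    return PruneResult(
        network=net, proportion=k / m, n_arcs=k, criteria=crit
    )


def read_weight_matrix(path) -> SignedWeightedNetwork:
    """Read a dense signed weight matrix CSV (labels in header row and first
    column, entry (i, j) = weight of i -> j)."""
    df = pd.read_csv(path, index_col=0, comment="#")
    labels = [str(c) for c in df.columns]
    if [str(r) for r in df.index] != labels:
        raise NetworkError("weight CSV row labels must match column labels")
    return SignedWeightedNetwork(df.to_numpy(dtype=float), labels)


def write_weight_matrix(wm: SignedWeightedNetwork, path, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(wm.weights, index=wm.labels, columns=wm.labels).to_csv(fh)
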