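"""Direction-randomisation null model.

The null destroys edge-direction information while preserving the undirected
skeleton: every connected pair of vertices is independently reassigned to one
of the three states (pure forward, pure backward, reciprocal) with
probability 1/3 each.  Under this null the blockwise-normalised signature of
every vertex converges to fixed expectation blocks that depend only on the
equiprobable-state model, not on the skeleton:

* degrees: (1/3, 1/3, 1/3)
* wedge classes: (1, 1, 2, 2, 2, 1) / 9
* triangle classes: (6, 2, 3, 3, 6, 6, 1) / 27

Those probabilities are *derived in code* by enumerating all equiprobable
orientation assignments of a wedge's two edges (3^2) and a triangle's three
edges (3^3) and classifying each outcome — not hard-coded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .counts import SIGNATURE_COLUMNS, signature_array
from .network import DirectedNetwork, EdgeType
from .oracle import (
    TRIANGLE_CLASSES,
    WEDGE_CLASSES,
    classify_triangle,
    classify_wedge_center,
)

__all__ = [
    "flip_directions",
    "wedge_flip_probabilities",
    "triangle_flip_probabilities",
    "flip_expectation",
    "convergence_check",
]


def flip_directions(g: DirectedNetwork, seed) -> DirectedNetwork:
    """Randomise edge directions: every connected pair is independently set
    to pure i->j, pure j->i, or reciprocal with probability 1/3 each.  The
    set of connected pairs (undirected skeleton) is exactly preserved."""
    rng = np.random.default_rng(seed)
    pairs = sorted({(min(i, j), max(i, j)) for i, j in g.arcs})
    states = rng.integers(0, 3, size=len(pairs))
    arcs = []
    for (i, j), s in zip(pairs, states):
        if s == 0:
            arcs.append((i, j))
        elif s == 1:
            arcs.append((j, i))
        else:
            arcs.extend([(i, j), (j, i)])
    return DirectedNetwork(g.labels, arcs)


@lru_cache(maxsize=1)
def wedge_flip_probabilities() -> np.ndarray:
    """Probability of each wedge class for a 2-edge star under uniform
    orientation of each edge over {out, in, reciprocal} (enumerates 3^2
    equiprobable assignments)."""
    counts = {c: 0 for c in WEDGE_CLASSES}
    for a, b in itertools.product(EdgeType, repeat=2):
        counts[classify_wedge_center(a, b)] += 1
    return np.array([counts[c] for c in WEDGE_CLASSES], dtype=float) / 9.0


@lru_cache(maxsize=1)
def triangle_flip_probabilities() -> np.ndarray:
    """Probability of each triangle class under uniform orientation of the
    three edges (enumerates 3^3 equiprobable assignments)."""

    def pair_arcs(u, v, s):
        return {(u, v)} if s == 0 else {(v, u)} if s == 1 else {(u, v), (v, u)}

    counts = {c: 0 for c in TRIANGLE_CLASSES}
    for s1, s2, s3 in itertools.product(range(3), repeat=3):
        arcs = pair_arcs(0, 1, s1) | pair_arcs(0, 2, s2) | pair_arcs(1, 2, s3)
        counts[classify_triangle(arcs, (0, 1, 2))] += 1
    return np.array([counts[c] for c in TRIANGLE_CLASSES], dtype=float) / 27.0


@dataclass(frozen=True)
class FlipExpectation:
    """Expected signatures under the direction-randomisation null."""

    normalized_blocks: np.ndarray  # 16-vector; blocks each sum to 1
    raw_counts: pd.DataFrame  # per-vertex expected raw counts (N x 16)


def _undirected_wedge_triangle_counts(g: DirectedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex counts on the undirected skeleton: induced wedges centred
    at i, and triangles through i."""
    u = g.typed_adjacency().skeleton.astype(np.int64)
    deg = u.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", u, u, u) // 2  # closed pairs at i
    wedges = deg * (deg - 1) // 2 - tri
    return wedges, tri


def flip_expectation(g: DirectedNetwork) -> FlipExpectation:
    """Analytic expectation of signatures under the flip null.

    Normalised blocks are skeleton-independent; expected raw counts per
    vertex are the skeleton quantities (degree, undirected wedge and triangle
    counts at the vertex) times the class probabilities.
    """
    wp, tp = wedge_flip_probabilities(), triangle_flip_probabilities()
    blocks = np.concatenate([np.full(3, 1.0 / 3.0), wp, tp])
    wedges, tris = _undirected_wedge_triangle_counts(g)
    deg = g.typed_adjacency().skeleton.sum(axis=1)
    raw = np.concatenate(
        [
            np.outer(deg, np.full(3, 1.0 / 3.0)),
            np.outer(wedges, wp),
            np.outer(tris, tp),
        ],
        axis=1,
    )
    return FlipExpectation(
        normalized_blocks=blocks,
        raw_counts=pd.DataFrame(raw, index=list(g.labels), columns=list(SIGNATURE_COLUMNS)),
    )


def convergence_check(g: DirectedNetwork, reps: int, seed) -> pd.DataFrame:
    """Monte-Carlo check that ensemble means of normalised signatures match
    the analytic flip expectation.

    Each flip yields one independent sample: the across-vertex mean of the
    blockwise-normalised signatures (per block, vertices with a degenerate —
    zero-total — block are excluded; their denominator is fixed by the
    skeleton, so exclusion is the same set every flip).  Deviations from the
    expectation are reported in standard-error units (``z``) over the
    ``reps`` samples.  Blocks degenerate at every vertex (e.g. a skeleton
    with no triangles) get ``n_samples = 0`` and NaN statistics.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    exp = flip_expectation(g).normalized_blocks
    block_slices = (slice(0, 3), slice(3, 9), slice(9, 16))
    samples = np.full((reps, 16), np.nan)
    for r in range(reps):
        flipped = flip_directions(g, rng.integers(0, 2**31 - 1))
        sig = signature_array(flipped).astype(float)
        for sl in block_slices:
            totals = sig[:, sl].sum(axis=1)
            ok = totals > 0
            if ok.any():
                samples[r, sl] = (sig[ok, sl] / totals[ok, None]).mean(axis=0)
    nobs = np.isfinite(samples).sum(axis=0)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(samples, axis=0)
        sd = np.nanstd(samples, axis=0, ddof=1)
        se = sd / np.sqrt(np.maximum(nobs, 1))
        z = (mean - exp) / se
    return pd.DataFrame(
        {
            "expected": exp,
            "mean": mean,
            "se": se,
            "z": z,
            "n_samples": nobs.astype(int),
        },
        index=list(SIGNATURE_COLUMNS),
    )
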