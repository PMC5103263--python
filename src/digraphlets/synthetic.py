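"""Synthetic inputs: random directed graphs and GCA-like signed cohorts.

Two generators make every pipeline stage testable without external data:

* :func:`random_digraph` — each unordered vertex pair is connected
  independently with probability ``p_arc``; a connected pair becomes a
  reciprocal dyad with probability ``p_rec``, otherwise a uniformly oriented
  pure arc.

* :func:`gca_cohort` — dense signed weight matrices emulating
  Granger-causality coefficient outputs for a cohort of subjects: a shared
  base matrix (log-normal magnitudes, i.i.d. signs, optional hub rows for
  degree heterogeneity) plus independent per-subject Gaussian perturbation,
  so downstream cohort consensus has common structure to find.

Defaults mirror the study conditions the package targets: 116 regions
(AAL-atlas size), 40 subjects, and a sign mixture of roughly half excitatory
entries; magnitudes are log-normal so that proportional thresholding removes
a genuinely heavy tail.  Everything is deterministic under the mandatory
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DirectedNetwork
from .preprocess import SignedWeightedNetwork

__all__ = ["GeneratorConfig", "random_digraph", "gca_cohort"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic generators.

    n
        Vertex (region) count; 116 matches the AAL atlas parcellation.
    p_arc, p_rec
        Pair-connection and conditional-reciprocity probabilities for
        :func:`random_digraph`.
    weight_scale
        Log-normal sigma of weight magnitudes in :func:`gca_cohort`.
    sign_fraction
        Fraction of positive (excitatory) entries in the base matrix.
    noise_scale
        Standard deviation of the per-subject additive Gaussian perturbation,
        relative to the median base magnitude.
    n_hubs, hub_boost
        Number of rows given systematically larger outgoing magnitudes, and
        their multiplicative boost (degree heterogeneity after pruning).
    subjects
        Cohort size; 40 matches the targeted study.
    seed
        Mandatory; all randomness flows from it.
    """

    seed: int
    n: int = 116
    p_arc: float = 0.25
    p_rec: float = 0.3
    weight_scale: float = 1.0
    sign_fraction: float = 0.5
    noise_scale: float = 0.25
    n_hubs: int = 8
    hub_boost: float = 2.0
    subjects: int = 40

    def __post_init__(self):
        for name in ("p_arc", "p_rec", "sign_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n < 1 or self.subjects < 1:
            raise ValueError("n and subjects must be positive")


def random_digraph(cfg: GeneratorConfig) -> DirectedNetwork:
    """Random directed graph with tunable arc and reciprocity probabilities.

    Each unordered pair is connected with ``p_arc``; connected pairs are
    reciprocal with ``p_rec`` else oriented uniformly at random.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    labels = [f"v{k}" for k in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    connected = rng.random(len(iu)) < cfg.p_arc
    # states for connected pairs: 0 fwd, 1 bwd, 2 reciprocal
    rec = rng.random(len(iu)) < cfg.p_rec
    fwd = rng.random(len(iu)) < 0.5
    arcs: list[tuple[int, int]] = []
    for i, j, conn, r, f in zip(iu.tolist(), ju.tolist(), connected, rec, fwd):
        if not conn:
            continue
        if r:
            arcs.extend([(i, j), (j, i)])
        elif f:
            arcs.append((i, j))
        else:
            arcs.append((j, i))
    return DirectedNetwork(labels, arcs)


def gca_cohort(cfg: GeneratorConfig) -> list[SignedWeightedNetwork]:
    """Cohort of dense signed weight matrices: shared base + subject noise.

    The base matrix has log-normal magnitudes (``sigma = weight_scale``),
    signs positive with probability ``sign_fraction``, and ``n_hubs`` rows
    scaled by ``hub_boost``; each subject adds independent Gaussian noise of
    scale ``noise_scale`` times the median base magnitude.  Diagonals are
    zero throughout.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    labels = tuple(f"roi{k:03d}" for k in range(n))
    mags = rng.lognormal(mean=0.0, sigma=cfg.weight_scale, size=(n, n))
    signs = np.where(rng.random((n, n)) < cfg.sign_fraction, 1.0, -1.0)
    base = mags * signs
    if cfg.n_hubs > 0:
        hubs = rng.choice(n, size=min(cfg.n_hubs, n), replace=False)
        base[hubs, :] *= cfg.hub_boost
    np.fill_diagonal(base, 0.0)
    sigma = cfg.noise_scale * float(np.median(np.abs(mags)))
    cohort = []
    for _ in range(cfg.subjects):
        w = base + rng.normal(scale=sigma, size=(n, n))
        np.fill_diagonal(w, 0.0)
        cohort.append(SignedWeightedNetwork(w, labels))
    return cohort
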