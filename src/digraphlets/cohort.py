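"""Cohort-level aggregation: consensus matrices and the regional
excitatory-vs-inhibitory comparison.

A cohort is a set of subjects, each contributing one network (or an
excitatory/inhibitory pair) on a shared vertex (region) set.  The consensus
matrix records, for every pair of signature coordinates, the percentage of
subjects in which the pair is significantly correlated (r > threshold) or
anti-correlated (r < -threshold).  Subjects whose correlation is undefined
at an entry count as *not significant* there, keeping the denominator fixed
at the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counts import SIGNATURE_COLUMNS, signature_matrix
from .gcm import GraphletCorrelationMatrix, significance_mask
from .network import DirectedNetwork, read_edge_list

__all__ = [
    "ConsensusMatrix",
    "CohortRecord",
    "consensus",
    "consensus_mask",
    "regional_class_comparison",
    "read_manifest",
]


@dataclass(frozen=True)
class ConsensusMatrix:
    """Percent-of-subjects matrices for significant (anti-)correlation."""

    positive_pct: pd.DataFrame  # percentage in [0, 100]
    negative_pct: pd.DataFrame
    n_subjects: int


@dataclass(frozen=True)
class CohortRecord:
    """One subject's excitatory and inhibitory networks (same region set)."""

    subject_id: str
    excitatory: DirectedNetwork
    inhibitory: DirectedNetwork

    def __post_init__(self):
        if self.excitatory.labels != self.inhibitory.labels:
            raise ValueError(
                f"subject {self.subject_id}: excitatory and inhibitory networks "
                "must share the same labelled vertex set"
            )


def consensus(
    gcms: list[GraphletCorrelationMatrix], threshold: float = 0.7
) -> ConsensusMatrix:
    """Entrywise percentage of subjects with significant positive/negative
    correlation (strict ``|r| > threshold``)."""
    if not gcms:
        raise ValueError("need at least one subject GCM")
    shape = gcms[0].shape
    idx, cols = gcms[0].values.index, gcms[0].values.columns
    pos = np.zeros(shape)
    neg = np.zeros(shape)
    for c in gcms:
        if c.shape != shape:
            raise ValueError(f"GCM shape mismatch: {c.shape} vs {shape}")
        m = significance_mask(c, threshold).to_numpy()
        pos += m == 1
        neg += m == -1
    k = len(gcms)
    return ConsensusMatrix(
        positive_pct=pd.DataFrame(100.0 * pos / k, index=idx, columns=cols),
        negative_pct=pd.DataFrame(100.0 * neg / k, index=idx, columns=cols),
        n_subjects=k,
    )


def consensus_mask(m: ConsensusMatrix, min_percent: float = 60.0) -> pd.DataFrame:
    """Ternary mask of entries shared by *more than* ``min_percent`` of
    subjects: +1 (positive consensus), -1 (negative), 0 otherwise."""
    if not 0 < min_percent <= 100:
        raise ValueError(f"min_percent must be in (0, 100], got {min_percent}")
    pos = m.positive_pct.to_numpy()
    neg = m.negative_pct.to_numpy()
    out = np.zeros(pos.shape, dtype=np.int64)
    out[pos > min_percent] = 1
    out[neg > min_percent] = -1
    return pd.DataFrame(out, index=m.positive_pct.index, columns=m.positive_pct.columns)


@dataclass(frozen=True)
class RegionalComparison:
    """Per-region inhibitory-minus-excitatory differences and CI verdicts."""

    table: pd.DataFrame  # region, delta, verdict
    pct_greater_inhibitory: float
    pct_greater_excitatory: float
    ci: tuple[float, float]


def regional_class_comparison(
    cohort: list[CohortRecord],
    klass: str = "W_out",
    alpha: float = 0.05,
    strategy: str = "mean_ci",
) -> RegionalComparison:
    """Compare a signature coordinate between inhibitory and excitatory
    networks, region by region.

    For each region the across-subject mean difference
    ``delta = mean(count_inhibitory - count_excitatory)`` is computed for the
    chosen class.  Regions whose delta falls outside the two-sided
    ``(1 - alpha)`` confidence interval are labelled ``greater_in_inhibitory``
    (above the upper bound) or ``greater_in_excitatory`` (below the lower
    bound); the two label percentages over all regions are returned.

    strategy
        ``"mean_ci"`` (default): CI of the across-region mean delta,
        ``mean ± z * sd / sqrt(R)`` — a region is flagged when its delta is
        inconsistent with the cohort-average difference.
        ``"population"``: ``mean ± z * sd`` of the across-region delta
        distribution — only extreme-tail regions are flagged.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    if klass not in SIGNATURE_COLUMNS:
        raise ValueError(f"unknown signature class {klass!r}")
    labels = cohort[0].excitatory.labels
    for rec in cohort:
        if rec.excitatory.labels != labels:
            raise ValueError(
                f"subject {rec.subject_id}: region labels differ across cohort"
            )
    deltas = np.zeros(len(labels))
    for rec in cohort:
        exc = signature_matrix(rec.excitatory)[klass].to_numpy(dtype=float)
        inh = signature_matrix(rec.inhibitory)[klass].to_numpy(dtype=float)
        deltas += inh - exc
    deltas /= len(cohort)

    z = stats.norm.ppf(1 - alpha / 2)
    mu, sd = deltas.mean(), deltas.std(ddof=1)
    if strategy == "mean_ci":
        half = z * sd / np.sqrt(len(labels))
    elif strategy == "population":
        half = z * sd
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    lo, hi = mu - half, mu + half

    verdict = np.where(
        deltas > hi, "greater_in_inhibitory",
        np.where(deltas < lo, "greater_in_excitatory", "within_ci"),
    )
    table = pd.DataFrame(
        {"region": labels, "delta": deltas, "verdict": verdict}
    ).set_index("region")
    r = len(labels)
    return RegionalComparison(
        table=table,
        pct_greater_inhibitory=100.0 * float((verdict == "greater_in_inhibitory").sum()) / r,
        pct_greater_excitatory=100.0 * float((verdict == "greater_in_excitatory").sum()) / r,
        ci=(float(lo), float(hi)),
    )


def read_manifest(path) -> list[CohortRecord]:
    """Read a cohort manifest TSV: subject_id, excitatory_path, inhibitory_path
    (paths relative to the manifest's directory)."""
    base = Path(path).parent
    records = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"manifest line {ln}: expected 3 fields")
            sid, exc_p, inh_p = parts
            records.append(
                CohortRecord(
                    subject_id=sid,
                    excitatory=read_edge_list(base / exc_p),
                    inhibitory=read_edge_list(base / inh_p),
                )
            )
    return records
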