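"""Graphlet correlation matrices, vertex similarity and Ward clustering.

The graphlet correlation matrix (GCM) of a network is the 16 x 16 matrix of
Pearson correlation coefficients between the columns of its N x 16 signature
matrix.  It summarises the network's local direction patterns independently
of its size and volume.  Zero-variance signature columns (a class absent
from the whole network) leave the corresponding correlations *undefined*:
they are carried as NaN with an explicit mask, never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .counts import SIGNATURE_COLUMNS

__all__ = [
    "GraphletCorrelationMatrix",
    "graphlet_correlation_matrix",
    "significance_mask",
    "vertex_similarity",
    "cluster_vertices",
    "write_gcm",
    "read_gcm",
]


@dataclass(frozen=True)
class GraphletCorrelationMatrix:
    """16 x 16 Pearson matrix of signature columns with a defined-ness mask."""

    values: pd.DataFrame  # NaN where undefined
    defined: pd.DataFrame  # boolean

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _pearson_columns(x: np.ndarray) -> np.ndarray:
    """Column-pairwise Pearson coefficients; NaN for zero-variance columns."""
    xc = x - x.mean(axis=0)
    ss = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (xc.T @ xc) / np.outer(ss, ss)
    c[:, ss == 0] = np.nan
    c[ss == 0, :] = np.nan
    return np.clip(c, -1.0, 1.0, out=c)


def graphlet_correlation_matrix(s: pd.DataFrame) -> GraphletCorrelationMatrix:
    """Pearson correlations between all pairs of signature columns.

    Requires at least 3 vertices (rows); with fewer, a correlation is either
    degenerate or identically ±1 and carries no information.
    """
    if s.shape[0] < 3:
        raise ValueError(
            f"need at least 3 vertices to correlate signature columns, got {s.shape[0]}"
        )
    cols = list(s.columns)
    c = _pearson_columns(s.to_numpy(dtype=float))
    values = pd.DataFrame(c, index=cols, columns=cols)
    return GraphletCorrelationMatrix(values=values, defined=values.notna())


def significance_mask(
    c: GraphletCorrelationMatrix, threshold: float = 0.7
) -> pd.DataFrame:
    """Ternary mask: +1 where r > threshold, -1 where r < -threshold, else 0.

    Inequalities are strict; undefined entries map to 0.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    v = c.values.to_numpy()
    mask = np.zeros(v.shape, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        mask[v > threshold] = 1
        mask[v < -threshold] = -1
    return pd.DataFrame(mask, index=c.values.index, columns=c.values.columns)


def vertex_similarity(s: pd.DataFrame, i, j) -> float:
    """Pearson correlation of two vertices' signature rows (NaN if a row is
    constant: similarity is then undefined)."""
    a = s.loc[str(i)].to_numpy(dtype=float)
    b = s.loc[str(j)].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cluster_vertices(
    s: pd.DataFrame, k: int | None = None, log_scale: bool = True
):
    """Ward agglomerative clustering of vertices by their signature rows.

    Distances are Euclidean on log1p-transformed counts by default (raw
    counts are heavy-tailed and otherwise dominated by the degree block).
    Returns ``(leaf_order, labels)``: the dendrogram leaf ordering for
    heat-map display, and flat cluster labels (1..k) when ``k`` is given,
    else ``None``.
    """
    x = s.to_numpy(dtype=float)
    if log_scale:
        x = np.log1p(x)
    z = hierarchy.ward(x)
    order = [s.index[i] for i in hierarchy.leaves_list(z)]
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=s.index, name="cluster")
    return order, labels


def write_gcm(c: GraphletCorrelationMatrix, path, comments: list[str] | None = None) -> None:
    """Write the 16 x 16 GCM as CSV; undefined entries become empty cells."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        c.values.to_csv(fh)


def read_gcm(path) -> GraphletCorrelationMatrix:
    df = pd.read_csv(path, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError("GCM file must be square")
    return GraphletCorrelationMatrix(values=df, defined=df.notna())
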