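"""Coding/non-coding co-expression (CNC) screening by Pearson correlation.

Every (non-coding, coding) gene pair sharing the same samples is scored by
the Pearson correlation coefficient of its log2 intensity profiles; the
correlation p-value uses the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2)
with n-2 degrees of freedom, and Benjamini-Hochberg adjustment is applied
over the full family of tested pairs.  The published screen retains pairs
with |PCC| >= 0.995 and FDR < 0.05 — an extremely stringent cut that, at
n = 12 samples, is essentially never crossed by independent noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diffexpr import bh_fdr
from .normio import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_PCC_MIN = 0.995
DEFAULT_FDR_MAX = 0.05


@dataclass(frozen=True)
class CoexpressionEdge:
    """A retained non-coding <-> coding co-expression pair."""

    ncrna_id: str
    coding_id: str
    r: float
    p: float
    q: float


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def correlation_test(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n (t approximation, df = n-2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(np.clip(2.0 * stats.t.sf(abs(t), n - 2), 0.0, 1.0))


def cnc_network(
    nc_matrix: ExpressionMatrix,
    coding_matrix: ExpressionMatrix,
    pcc_min: float = DEFAULT_PCC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    group: str | None = None,
) -> list[CoexpressionEdge]:
    """All (ncRNA, coding) pairs passing |r| >= pcc_min and BH q < fdr_max.

    Correlation is computed on log2 intensities over the shared samples
    (optionally restricted to one group); the BH family is the full set of
    tested pairs.  Constant genes are skipped with a warning.  The sign of r
    is retained on each edge for downstream direction rules.
    """
    if nc_matrix.sample_ids != coding_matrix.sample_ids:
        raise ValueError("matrices must share the same samples in the same order")
    samples = nc_matrix.sample_ids
    if group is not None:
        samples = nc_matrix.samples_in_group(group)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    X = np.log2(nc_matrix.values[samples].to_numpy(float))
    Y = np.log2(coding_matrix.values[samples].to_numpy(float))
    nc_ids = np.array(nc_matrix.gene_ids)
    coding_ids = np.array(coding_matrix.gene_ids)

    def _standardize(M, ids, label):
        sd = M.std(axis=1, ddof=0)
        keep = sd > 0
        if not keep.all():
            log.warning("cnc_network: skipping %d constant %s gene(s)",
                        int((~keep).sum()), label)
        Z = (M[keep] - M[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        return Z, ids[keep]

    Zx, nc_ids = _standardize(X, nc_ids, "non-coding")
    Zy, coding_ids = _standardize(Y, coding_ids, "coding")
    if Zx.shape[0] == 0 or Zy.shape[0] == 0:
        return []
    R = np.clip(Zx @ Zy.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt(n - 2) / np.sqrt(1.0 - R * R)
    P = np.where(np.abs(R) == 1.0, 0.0, np.clip(2.0 * stats.t.sf(np.abs(T), n - 2), 0, 1))
    Q = bh_fdr(P.ravel()).reshape(P.shape)
    keep = (np.abs(R) >= pcc_min) & (Q < fdr_max)
    edges = [
        CoexpressionEdge(nc_ids[i], coding_ids[j], float(R[i, j]),
                         float(P[i, j]), float(Q[i, j]))
        for i, j in np.argwhere(keep)
    ]
    edges.sort(key=lambda e: (e.p, e.ncrna_id, e.coding_id))
    return edges


def edges_to_records(edges: list[CoexpressionEdge]) -> list[dict]:
    """Plain-dict view of an edge list (for TSV export)."""
    return [vars(e).copy() for e in edges]
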