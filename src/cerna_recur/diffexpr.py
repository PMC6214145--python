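"""Per-gene two-group testing, fold change, FDR, DE calling and qPCR utilities.

Fold change is computed on linear-scale group means (the microarray
convention); the two-group test is a Welch unequal-variance t-test on log2
intensities with a small variance floor so that degenerate (zero-variance)
fixtures do not crash.  Multiple testing is controlled with the
Benjamini-Hochberg step-up procedure.  Significance calling uses
class-specific thresholds: short RNAs (miRNA) are customarily called at
FC > 1.5, long transcripts (lncRNA/mRNA) at FC > 2.0, both with p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .normio import ExpressionMatrix

#: variance floor on the log2 scale, added to each group's variance
VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class DEThresholds:
    """Significance thresholds for one RNA class.

    ``strict_fc`` selects a strict (>) versus inclusive (>=) fold-change
    comparison; the conventional published filters are strict.
    """

    fc_min: float = 2.0
    p_max: float = 0.05
    strict_fc: bool = True

    def __post_init__(self) -> None:
        if not self.fc_min > 1:
            raise ValueError("fc_min must be > 1")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")


MIRNA_THRESHOLDS = DEThresholds(fc_min=1.5, p_max=0.05)
LONG_RNA_THRESHOLDS = DEThresholds(fc_min=2.0, p_max=0.05)

DEFAULT_THRESHOLDS = {
    "mirna": MIRNA_THRESHOLDS,
    "lncrna": LONG_RNA_THRESHOLDS,
    "mrna": LONG_RNA_THRESHOLDS,
}


def fold_change(ref_values, test_values) -> tuple[float, float, str]:
    """Linear fold change mean(test)/mean(ref) with direction.

    Returns ``(fc, log2fc, direction)`` where direction is 'up' if fc > 1,
    'down' if fc < 1 and 'none' at exactly 1.  Down-regulation by a factor f
    is conventionally reported as "f-fold down", i.e. 1/fc.
    """
    ref = np.asarray(ref_values, float)
    test = np.asarray(test_values, float)
    if ref.size == 0 or test.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(ref <= 0) or np.any(test <= 0):
        raise ValueError("intensities must be > 0")
    fc = test.mean() / ref.mean()
    log2fc = float(np.log2(fc))
    direction = "up" if fc > 1 else ("down" if fc < 1 else "none")
    return float(fc), log2fc, direction


def two_group_test(ref_values, test_values, var_floor: float = VAR_FLOOR):
    """Welch two-sample t-test (two-sided) on already log-scaled values.

    Returns ``(t, df, p)``.  A variance floor is added to each group's
    variance so identical groups yield t = 0, p = 1 rather than 0/0.
    """
    x = np.asarray(ref_values, float)
    y = np.asarray(test_values, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    t, df, p = _welch(x.reshape(1, -1), y.reshape(1, -1), var_floor)
    return float(t[0]), float(df[0]), float(p[0])


def _welch(x: np.ndarray, y: np.ndarray, var_floor: float = VAR_FLOOR):
    """Vectorized Welch test over rows of two (genes x replicates) arrays."""
    nx, ny = x.shape[1], y.shape[1]
    vx = x.var(axis=1, ddof=1) + var_floor
    vy = y.var(axis=1, ddof=1) + var_floor
    se2 = vx / nx + vy / ny
    t = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, np.clip(p, 0.0, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def passes_thresholds(fc, p, thr: DEThresholds) -> bool:
    """Apply the class FC/p filter to a single record."""
    if thr.strict_fc:
        fc_ok = fc > thr.fc_min or fc < 1.0 / thr.fc_min
    else:
        fc_ok = fc >= thr.fc_min or fc <= 1.0 / thr.fc_min
    return bool(fc_ok and p <= thr.p_max)


def call_differential(
    m: ExpressionMatrix,
    contrast: tuple[str, str],
    thresholds: DEThresholds = LONG_RNA_THRESHOLDS,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene DE table for ``contrast = (ref_group, test_group)``.

    Testing is on log2 intensities; fold change on linear group means.  When
    ``use_fdr`` is set, significance uses the BH-adjusted q instead of the
    raw p (both are always reported).  Columns: gene_id, mean_ref, mean_test,
    fc, log2fc, direction, p, q, neg_log10_p, significant.
    """
    ref_samples = m.samples_in_group(contrast[0])
    test_samples = m.samples_in_group(contrast[1])
    ref = m.values[ref_samples].to_numpy(float)
    test = m.values[test_samples].to_numpy(float)
    n = m.n_genes
    out = pd.DataFrame(index=pd.Index(m.gene_ids, name="gene_id"))
    if n == 0:
        for col in ("mean_ref", "mean_test", "fc", "log2fc", "p", "q", "neg_log10_p"):
            out[col] = np.array([], float)
        out["direction"] = np.array([], object)
        out["significant"] = np.array([], bool)
        return out.reset_index()
    mean_ref = ref.mean(axis=1)
    mean_test = test.mean(axis=1)
    fc = mean_test / mean_ref
    if ref.shape[1] < 2 or test.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group for testing")
    _, _, p = _welch(np.log2(ref), np.log2(test))
    q = bh_fdr(p)
    out["mean_ref"] = mean_ref
    out["mean_test"] = mean_test
    out["fc"] = fc
    out["log2fc"] = np.log2(fc)
    out["direction"] = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    out["p"] = p
    out["q"] = q
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(p)
    crit_p = q if use_fdr else p
    if thresholds.strict_fc:
        fc_ok = (fc > thresholds.fc_min) | (fc < 1.0 / thresholds.fc_min)
    else:
        fc_ok = (fc >= thresholds.fc_min) | (fc <= 1.0 / thresholds.fc_min)
    out["significant"] = fc_ok & (crit_p <= thresholds.p_max)
    return out.reset_index()


def de_counts(table: pd.DataFrame) -> dict[str, int]:
    """Up/down counts among significant genes of a DE table."""
    sig = table[table["significant"]]
    return {
        "up": int((sig["direction"] == "up").sum()),
        "down": int((sig["direction"] == "down").sum()),
        "total": int(len(sig)),
    }


def hierarchical_cluster(m, axis: str = "genes"):
    """Average-linkage agglomerative clustering with distance 1 - Pearson r.

    ``m`` may be an ExpressionMatrix (clustered on log2 intensities) or a
    plain DataFrame/array.  ``axis`` selects 'genes' (rows) or 'samples'
    (columns).  Returns a SciPy linkage matrix; ordering is deterministic.
    Items with zero variance have undefined correlation distance and raise.
    """
    if isinstance(m, ExpressionMatrix):
        data = m.log2().to_numpy(float)
        labels = m.gene_ids if axis == "genes" else m.sample_ids
    else:
        data = np.asarray(m, float)
        labels = None
    if axis == "samples":
        data = data.T
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'samples'")
    if data.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    if np.any(data.std(axis=1) == 0):
        idx = int(np.flatnonzero(data.std(axis=1) == 0)[0])
        name = labels[idx] if labels else idx
        raise ValueError(f"zero-variance item {name!r}: correlation distance undefined")
    dist = pdist(data, metric="correlation")
    return hierarchy.linkage(dist, method="average")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR condition: target and reference threshold cycles (Ct)."""

    sample_id: str
    group: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not (np.isfinite(ct) and ct > 0):
                raise ValueError("Ct values must be finite and > 0")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control;
    returns 2**(-ddCt), always positive.
    """
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))
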