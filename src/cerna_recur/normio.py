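"""Expression-matrix container, TSV round-trip, normalization and detection filtering.

The container holds linear-scale intensities (genes x samples) together with
per-sample group labels (three-phase design: A = control, B = elicitation,
C = remission, but any label set is accepted) and optional per-cell detection
flags (P = Present, M = Marginal, A = Absent), mirroring single-channel
microarray feature-extraction output.

Two normalization schemes are provided, matching common array practice:

* ``quantile_normalize`` forces every sample onto the common empirical
  distribution obtained by averaging the per-rank values across samples
  (used for long transcript arrays).
* ``median_normalize`` rescales each sample so that the median of a
  high-confidence reference gene set (intensity >= a floor in *all*
  samples) is equal across samples (used for short-RNA arrays).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical detection-flag symbols
FLAG_PRESENT = "P"
FLAG_MARGINAL = "M"
FLAG_ABSENT = "A"
VALID_FLAGS = frozenset({FLAG_PRESENT, FLAG_MARGINAL, FLAG_ABSENT})

_FLAG_ALIASES = {
    "P": "P", "PRESENT": "P",
    "M": "M", "MARGINAL": "M",
    "A": "A", "ABSENT": "A",
}

#: row label of the second header line in the TSV layout
GROUP_ROW_LABEL = "group"


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity table with group labels and optional flags.

    Parameters
    ----------
    values
        DataFrame of strictly positive, finite linear-scale intensities;
        index = gene ids, columns = sample ids, both unique.
    groups
        Series mapping sample id -> group label, aligned with ``values``
        columns.
    flags
        Optional DataFrame of detection flags ('P'/'M'/'A'), same shape and
        labels as ``values``.
    """

    values: pd.DataFrame
    groups: pd.Series
    flags: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
            bad = np.argwhere(~(np.isfinite(arr) & (arr > 0)))[0]
            raise ValueError(
                "intensities must be finite and > 0; offending cell "
                f"gene={self.values.index[bad[0]]!r} sample={self.values.columns[bad[1]]!r}"
            )
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing}")
        if self.flags is not None:
            if not (
                self.flags.shape == self.values.shape
                and self.flags.index.equals(self.values.index)
                and self.flags.columns.equals(self.values.columns)
            ):
                raise ValueError("flags must share the values table's shape and labels")
            bad_flags = set(np.unique(self.flags.to_numpy())) - VALID_FLAGS
            if bad_flags:
                raise ValueError(f"invalid flag symbols: {sorted(bad_flags)}")

    # ------------------------------------------------------------------ views

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self) -> pd.DataFrame:
        """Log2-scale view of the intensities."""
        return np.log2(self.values)

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.groups.index[self.groups == group].tolist()
        if not sel:
            raise KeyError(f"no samples in group {group!r}")
        return sel

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        flags = self.flags.loc[gene_ids] if self.flags is not None else None
        return ExpressionMatrix(self.values.loc[gene_ids], self.groups.copy(), flags)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        flags = self.flags[sample_ids] if self.flags is not None else None
        return ExpressionMatrix(self.values[sample_ids], self.groups[sample_ids], flags)

    # ------------------------------------------------------------------- I/O

    def write_tsv(self, path, flags_path=None) -> None:
        """Write the matrix (and optionally flags) in the two-header TSV layout."""
        _write_two_header_tsv(path, self.values, self.groups)
        if flags_path is not None:
            if self.flags is None:
                raise ValueError("matrix carries no flags")
            _write_two_header_tsv(flags_path, self.flags, self.groups)


def _write_two_header_tsv(path, table: pd.DataFrame, groups: pd.Series) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, table.columns)) + "\n")
        fh.write(GROUP_ROW_LABEL + "\t" + "\t".join(groups[c] for c in table.columns) + "\n")
        for gid, row in table.iterrows():
            fh.write(str(gid) + "\t" + "\t".join(_cell(v) for v in row) + "\n")


def _cell(v) -> str:
    return v if isinstance(v, str) else format(float(v), ".10g")


def read_expression_table(path, flags_path=None) -> ExpressionMatrix:
    """Read a two-header expression TSV (sample ids, then group labels).

    Raises ``ValueError`` naming the offending gene row and sample column for
    malformed numeric cells, and on ragged rows, duplicate ids or
    non-positive intensities.
    """
    raw = _read_two_header_tsv(path)
    values, groups = raw
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        gi, sj = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric intensity in {path}: gene={values.index[gi]!r} "
            f"sample={values.columns[sj]!r} value={values.iat[gi, sj]!r}"
        )
    flags = None
    if flags_path is not None:
        ftab, fgroups = _read_two_header_tsv(flags_path)
        flags = ftab.apply(lambda col: col.str.strip().str.upper().map(_FLAG_ALIASES))
        if flags.isna().any().any():
            gi, sj = np.argwhere(flags.isna().to_numpy())[0]
            raise ValueError(
                f"invalid detection flag in {flags_path}: gene={ftab.index[gi]!r} "
                f"sample={ftab.columns[sj]!r}"
            )
    return ExpressionMatrix(numeric, groups, flags)


def _read_two_header_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected sample-id and group header lines")
    header = lines[0].split("\t")
    group_row = lines[1].split("\t")
    sample_ids = header[1:]
    if group_row[0] != GROUP_ROW_LABEL:
        raise ValueError(f"{path}: second line must start with {GROUP_ROW_LABEL!r}")
    if len(group_row) != len(header):
        raise ValueError(f"{path}: group line has {len(group_row) - 1} labels "
                         f"for {len(sample_ids)} samples")
    rows, index = [], []
    for k, ln in enumerate(lines[2:], start=3):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}: ragged row at line {k} (gene {parts[0]!r})")
        index.append(parts[0])
        rows.append(parts[1:])
    table = pd.DataFrame(rows, index=index, columns=sample_ids, dtype=object)
    groups = pd.Series(group_row[1:], index=sample_ids, dtype=object)
    return table, groups


# ------------------------------------------------------------- normalization

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force all samples onto the mean empirical distribution.

    Each gene receives the across-sample mean of the values holding its
    within-sample rank; ties within a sample receive the average of the tied
    ranks' means.  Idempotent, and the sorted value vector of every sample is
    identical afterwards.
    """
    vals = m.values.to_numpy(float)
    n_genes, n_samples = vals.shape
    if n_samples < 1:
        raise ValueError("need at least one sample")
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    mean_at_rank = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        # runs of tied values share the mean of their ranks' reference values
        boundaries = np.flatnonzero(col_sorted[1:] != col_sorted[:-1]) + 1
        starts = np.concatenate(([0], boundaries))
        sums = np.add.reduceat(mean_at_rank, starts)
        lengths = np.diff(np.concatenate((starts, [n_genes])))
        run_means = sums / lengths
        assigned = np.repeat(run_means, lengths)
        out[order[:, j], j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.groups.copy(),
        None if m.flags is None else m.flags.copy(),
    )


def median_normalize(m: ExpressionMatrix, ref_min_intensity: float = 30.0) -> ExpressionMatrix:
    """Equalize per-sample medians of the reference gene set.

    The reference set is the genes with intensity >= ``ref_min_intensity`` in
    every sample (default floor 30, the usual short-RNA array convention).
    Each sample is scaled by (grand mean of reference medians) / (its own
    reference median), preserving within-sample rank order and keeping values
    on the original intensity scale.
    """
    vals = m.values.to_numpy(float)
    ref_mask = (vals >= ref_min_intensity).all(axis=1)
    if not ref_mask.any():
        raise ValueError(
            f"empty reference set: no gene has intensity >= {ref_min_intensity} in all samples"
        )
    ref_medians = np.median(vals[ref_mask], axis=0)
    scale = ref_medians.mean() / ref_medians
    out = vals * scale[np.newaxis, :]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.groups.copy(),
        None if m.flags is None else m.flags.copy(),
    )


def filter_detected(m: ExpressionMatrix, min_flagged_samples: int = 3) -> ExpressionMatrix:
    """Keep genes flagged Present or Marginal in >= ``min_flagged_samples`` samples.

    The default of 3 follows the convention of requiring detection in at
    least three arrays of a 12-array three-group design.
    """
    if m.flags is None:
        raise ValueError("detection filtering requires flags")
    detected = m.flags.isin([FLAG_PRESENT, FLAG_MARGINAL]).sum(axis=1)
    keep = detected[detected >= min_flagged_samples].index
    dropped = m.n_genes - len(keep)
    if dropped:
        log.info("filter_detected: dropped %d/%d genes", dropped, m.n_genes)
    return m.subset_genes(keep)
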