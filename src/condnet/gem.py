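"""Gene expression matrix (GEM) I/O and preprocessing.

The GEM is a genes x samples :class:`pandas.DataFrame` (gene IDs as the
index, sample IDs as the columns) of nonnegative FPKM-like values, with
``NaN`` for missing cells.  Preprocessing follows the standard recipe for
correlation-network input: log2 transform, Kolmogorov-Smirnov outlier
sample removal, then quantile normalization.

Gene identifiers in the ``ENSGxxxxxxxxxxx;SYMBOL`` dialect are carried
verbatim; nothing in this module parses them apart.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "load_gem",
    "save_gem",
    "log_transform",
    "detect_outliers",
    "drop_outliers",
    "quantile_normalize",
]


@dataclass
class PreprocessReport:
    """Per-sample outlier-screen result.

    Attributes
    ----------
    d_statistic
        Two-sample KS statistic ``D`` per sample, in ``[0, 1]``, comparing
        the sample's value distribution against the pooled values of all
        other samples.  ``NaN`` for samples excluded from testing.
    flagged
        Boolean per sample; ``True`` iff ``D > d_threshold``.
    d_threshold
        Threshold applied.
    skipped
        Samples with too few non-missing values to test.
    """

    d_statistic: pd.Series
    flagged: pd.Series
    d_threshold: float
    skipped: list[str] = field(default_factory=list)

    @property
    def outliers(self) -> list[str]:
        return list(self.flagged.index[self.flagged])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"D": self.d_statistic, "flagged": self.flagged.astype(int)}
        ).rename_axis("sample_id")

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")


def _check_unique(values, kind: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicate {kind} ID: {dup!r}")


def load_gem(path, *, sep: str = "\t", na_values=("NA", "na", "")) -> pd.DataFrame:
    """Read a GEM table: header row of sample IDs, first column gene IDs.

    Unparseable cells become missing; their count is logged.  Duplicate
    gene or sample IDs and empty matrices are hard errors.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, na_values=list(na_values),
                      keep_default_na=False, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    _check_unique(raw.index, "gene")
    _check_unique(raw.columns, "sample")
    values = raw.apply(pd.to_numeric, errors="coerce")
    n_bad = int((values.isna() & raw.notna()).sum().sum())
    if n_bad:
        logger.warning("load_gem: %d unparseable cells set to missing", n_bad)
    values.index.name = "gene_id"
    return values


def save_gem(gem: pd.DataFrame, path, *, sep: str = "\t") -> None:
    gem.to_csv(path, sep=sep, na_rep="NA")


def log_transform(gem: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Apply ``x -> log2(x + pseudocount)`` elementwise.

    Requires nonnegative input.  With ``pseudocount == 0`` any zero cells
    would map to ``-inf``; they become missing instead, with a warning.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    vals = gem.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("log_transform requires nonnegative values")
    if pseudocount == 0:
        n_zero = int((vals == 0).sum())
        if n_zero:
            warnings.warn(
                f"log_transform with pseudocount=0: {n_zero} zero cells set to missing",
                RuntimeWarning,
                stacklevel=2,
            )
            vals = np.where(vals == 0, np.nan, vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(vals + pseudocount)
    return pd.DataFrame(out, index=gem.index, columns=gem.columns)


def detect_outliers(
    gem: pd.DataFrame, d_threshold: float = 0.15, min_values: int = 10
) -> PreprocessReport:
    """Flag outlier samples by a leave-one-out two-sample KS test.

    Each sample's non-missing value distribution is compared against the
    pooled non-missing values of every *other* sample; a sample is
    flagged iff the KS statistic ``D`` exceeds ``d_threshold``.  Samples
    with fewer than ``min_values`` non-missing values are skipped (warned,
    never flagged).
    """
    if gem.shape[1] < 3:
        raise ValueError("outlier detection requires at least 3 samples")
    vals = gem.to_numpy(dtype=float)
    d = pd.Series(np.nan, index=gem.columns, dtype=float)
    skipped: list[str] = []
    all_values = vals[np.isfinite(vals)]
    for j, sample in enumerate(gem.columns):
        col = vals[:, j]
        col = col[np.isfinite(col)]
        if col.size < min_values:
            skipped.append(sample)
            continue
        other = vals[:, np.arange(vals.shape[1]) != j].ravel()
        other = other[np.isfinite(other)]
        d[sample] = stats.ks_2samp(col, other, method="asymp").statistic
    if skipped:
        warnings.warn(
            f"detect_outliers: {len(skipped)} samples with <{min_values} values skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    if all_values.size == 0:
        raise ValueError("matrix has no finite values")
    flagged = d > d_threshold
    return PreprocessReport(d, flagged.fillna(False).astype(bool), d_threshold, skipped)


def drop_outliers(gem: pd.DataFrame, report: PreprocessReport) -> pd.DataFrame:
    """Remove the samples the report flagged."""
    return gem.drop(columns=report.outliers)


def _reference_distribution(vals: np.ndarray) -> np.ndarray:
    """Mean of per-column order statistics, aligned to the longest column."""
    n_rows, n_cols = vals.shape
    counts = np.array([np.isfinite(vals[:, j]).sum() for j in range(n_cols)])
    m = counts.max()
    acc = np.zeros(m)
    grid = np.linspace(0.0, 1.0, m)
    for j in range(n_cols):
        col = np.sort(vals[np.isfinite(vals[:, j]), j])
        if col.size == m:
            acc += col
        else:
            acc += np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
    return acc / n_cols


def quantile_normalize(gem: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common reference distribution.

    The reference is the across-sample mean of order statistics.  Within a
    column, tied values all receive the mean of the reference values at
    the rank positions the tie spans, so rank order is preserved and,
    for complete data, every column ends up with the identical sorted
    value multiset.

    Columns with missing cells are mapped through linear interpolation of
    the reference quantile function at their own (shorter) rank grid.
    An all-missing column is a hard error.
    """
    if gem.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    vals = gem.to_numpy(dtype=float)
    counts = np.isfinite(vals).sum(axis=0)
    if (counts == 0).any():
        bad = gem.columns[counts == 0][0]
        raise ValueError(f"all-missing sample column: {bad!r}")
    ref = _reference_distribution(vals)
    m = ref.size
    out = np.full_like(vals, np.nan)
    for j in range(vals.shape[1]):
        finite = np.isfinite(vals[:, j])
        col = vals[finite, j]
        k = col.size
        if k == m:
            target = ref
        else:
            target = np.interp(
                np.linspace(0.0, 1.0, k), np.linspace(0.0, 1.0, m), ref
            )
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        normalized = np.empty(k)
        start = 0
        while start < k:
            stop = start
            while stop + 1 < k and sorted_vals[stop + 1] == sorted_vals[start]:
                stop += 1
            normalized[order[start : stop + 1]] = target[start : stop + 1].mean()
            start = stop + 1
        res = np.full(vals.shape[0], np.nan)
        res[finite] = normalized
        out[:, j] = res
    return pd.DataFrame(out, index=gem.index, columns=gem.columns)


def preprocess(
    gem: pd.DataFrame,
    pseudocount: float = 1.0,
    d_threshold: float = 0.15,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """log2 -> KS outlier removal (single pass) -> quantile normalization."""
    logged = log_transform(gem, pseudocount)
    report = detect_outliers(logged, d_threshold)
    kept = drop_outliers(logged, report)
    return quantile_normalize(kept), report
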