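"""Input handling for probeset-level expression matrices.

Reads and validates tab-delimited log2-intensity matrices and sample sheets,
quantile-normalizes across arrays, locates the empirical low-expression cutoff
from the bimodal intensity distribution, filters low genes, and flags outlier
arrays from inter-array correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import AnalysisError, SchemaError

logger = logging.getLogger(__name__)

#: Fallback low-expression cutoff (log2 scale) when the intensity distribution
#: does not show a detectable low mode.
DEFAULT_LOW_CUTOFF = 4.0

SAMPLE_SHEET_COLUMNS = ("sample_id", "phenotype", "condition")


@dataclass
class ExpressionMatrix:
    """Probesets x samples log2-intensity grid with per-sample annotations.

    ``values`` is indexed by probeset ID with one column per sample.
    ``samples`` is indexed by sample ID and carries at least ``phenotype`` and
    ``condition`` (plus optional ``learning_index``); rows are aligned to the
    matrix columns on construction.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise SchemaError(f"duplicate probeset ID: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise SchemaError(f"duplicate sample ID: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.columns[
                [not np.issubdtype(t, np.number) for t in self.values.dtypes]
            ][0]
            raise SchemaError(f"non-numeric values in column {bad!r}")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise SchemaError(
                f"non-finite value at probeset {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns.copy())
        else:
            missing = self.values.columns.difference(self.samples.index)
            if len(missing):
                raise SchemaError(
                    f"samples missing from annotations: {list(missing)}"
                )
            # keyed join: align annotation rows to matrix column order
            self.samples = self.samples.loc[self.values.columns]

    @property
    def probeset_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """New matrix sharing annotations (restricted to ``values`` columns)."""
        return ExpressionMatrix(values, self.samples.loc[values.columns])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return self.with_values(self.values[list(sample_ids)])

    def gene_means(self) -> pd.Series:
        return self.values.mean(axis=1)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "probeset_id"
        out.to_csv(path, sep="\t")

    def sample_sheet_to_tsv(self, path) -> None:
        out = self.samples.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass
class QcReport:
    """Outlier-array QC summary.

    ``median_correlations`` holds each sample's median Pearson correlation to
    all other samples; ``flagged_outliers`` the arrays falling below the Tukey
    fence Q1 - 1.5*IQR of those medians. ``cutoff_used``/``n_genes_retained``
    are filled in by pipeline code once low-expression filtering has run.
    """

    median_correlations: pd.Series
    flagged_outliers: list[str]
    cutoff_used: float | None = None
    n_genes_retained: int | None = None

    def to_dict(self) -> dict:
        return {
            "median_correlations": {
                k: float(v) for k, v in self.median_correlations.items()
            },
            "flagged_outliers": list(self.flagged_outliers),
            "cutoff_used": self.cutoff_used,
            "n_genes_retained": self.n_genes_retained,
        }


def read_matrix(path) -> ExpressionMatrix:
    """Read a tab-delimited probeset x sample matrix (first column probeset_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "probeset_id":
        raise SchemaError(
            f"{path.name}: first column must be 'probeset_id', got {df.index.name!r}"
        )
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise SchemaError(
                f"{path.name}: non-numeric value {bad.iloc[0]!r} in column "
                f"{col!r} (probeset {bad.index[0]!r})"
            )
    return ExpressionMatrix(df.astype(float))


def read_sample_sheet(path, matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Attach a sample sheet (sample_id, phenotype, condition[, learning_index]).

    Annotations are joined by sample ID, so sheet row order need not match the
    matrix column order. Every matrix sample must appear in the sheet.
    """
    path = Path(path)
    sheet = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise SchemaError(f"{path.name}: missing columns {missing_cols}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{path.name}: duplicate sample_id {dup!r}")
    sheet = sheet.set_index("sample_id")
    missing = matrix.sample_ids.difference(sheet.index)
    if len(missing):
        raise SchemaError(
            f"{path.name}: samples missing from sheet: {list(missing)}"
        )
    extra = sheet.index.difference(matrix.sample_ids)
    if len(extra):
        logger.info("sample sheet has %d samples not in matrix; ignored", len(extra))
    if "learning_index" in sheet.columns:
        sheet["learning_index"] = pd.to_numeric(sheet["learning_index"])
    return ExpressionMatrix(matrix.values, sheet.loc[matrix.sample_ids])


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array onto the common distribution of sorted-value means.

    Each sample's i-th smallest value is replaced by the across-sample mean of
    i-th smallest values; ranks (hence within-sample order up to ties) are
    preserved. Ties are broken by stable row order, which makes the operation
    exactly idempotent. A single-sample matrix is returned unchanged with a
    warning.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile_normalize: <2 samples, returning input unchanged")
        return matrix.with_values(matrix.values.copy())
    vals = matrix.values.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    np.put_along_axis(out, order, ref[:, None], axis=0)
    return matrix.with_values(
        pd.DataFrame(out, index=matrix.probeset_ids, columns=matrix.sample_ids)
    )


def detect_low_cutoff(
    matrix: ExpressionMatrix,
    default: float = DEFAULT_LOW_CUTOFF,
    grid_points: int = 512,
) -> float:
    """Locate the low-expression cutoff from the bimodal intensity profile.

    A Gaussian kernel density (Scott bandwidth) of per-gene mean intensities is
    scanned for its two highest modes; the cutoff is the density minimum
    between them. If fewer than two modes are found the configured default
    (log2 = 4 by convention for GCRMA-style data) is returned.
    """
    means = matrix.gene_means().to_numpy()
    if means.std() == 0:
        logger.info("detect_low_cutoff: degenerate intensities, default %.3g", default)
        return float(default)
    kde = gaussian_kde(means)
    grid = np.linspace(means.min(), means.max(), grid_points)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=0.05 * dens.max())
    if len(peaks) < 2:
        logger.info("detect_low_cutoff: no bimodality, default %.3g", default)
        return float(default)
    top2 = np.sort(peaks[np.argsort(dens[peaks])[-2:]])
    lo, hi = top2
    dip = lo + int(np.argmin(dens[lo : hi + 1]))
    if dens[dip] >= 0.95 * min(dens[lo], dens[hi]):
        logger.info("detect_low_cutoff: modes not separated, default %.3g", default)
        return float(default)
    return float(grid[dip])


def filter_low_expression(
    matrix: ExpressionMatrix, cutoff: float
) -> ExpressionMatrix:
    """Drop genes whose across-sample mean intensity is strictly below ``cutoff``."""
    if not np.isfinite(cutoff) and cutoff > 0:
        raise AnalysisError("cutoff must be finite or -inf")
    keep = matrix.gene_means() >= cutoff
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise AnalysisError(
            f"low-expression filter at cutoff {cutoff:.3g} removed every gene"
        )
    logger.info("filter_low_expression: removed %d of %d genes", n_removed, len(keep))
    return matrix.with_values(matrix.values.loc[keep])


def detect_outlier_arrays(
    matrix: ExpressionMatrix, max_flag_fraction: float = 0.2
) -> QcReport:
    """Flag arrays with anomalously low median inter-array correlation.

    Each sample's median Pearson correlation to all other samples is computed;
    samples strictly below Q1 - 1.5*IQR of those medians are flagged, capped at
    ``max_flag_fraction`` of samples (lowest medians kept). Fewer than 4
    samples yields an empty report with a warning.
    """
    n = matrix.n_samples
    if n < 4:
        warnings.warn("detect_outlier_arrays: <4 samples, skipping QC")
        return QcReport(
            pd.Series(np.nan, index=matrix.sample_ids), flagged_outliers=[]
        )
    corr = np.corrcoef(matrix.values.to_numpy().T)
    np.fill_diagonal(corr, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(corr, axis=1)
    medians = pd.Series(med, index=matrix.sample_ids)
    q1, q3 = np.percentile(med, [25, 75])
    fence = q1 - 1.5 * (q3 - q1)
    flagged = medians.index[medians < fence]  # strict: boundary equality kept
    max_n = int(np.floor(max_flag_fraction * n))
    if len(flagged) > max_n:
        flagged = medians.loc[flagged].nsmallest(max_n).index
    return QcReport(medians, flagged_outliers=sorted(flagged))
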