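"""Cross-dataset d-statistic concordance and gene-set distribution shifts.

Two independently run experiments over the same platform cannot be compared at
the intensity level, but their per-probeset d-statistics can: probesets are
paired by identifier, concordance is the Pearson correlation of the paired
d's, and a named gene set's behaviour is tested by comparing its members'
d-statistic distribution against the background of all tested genes
(rank-sum by default, with KS and random-set permutation alternatives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .genesets import GeneSet
from .samstat import SamResult

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
MIN_SET_SIZE = 5
SHIFT_METHODS = ("ranksum", "ks", "perm")


@dataclass
class ConcordanceResult:
    """Pearson concordance of paired d-statistics across two analyses."""

    n_paired: int
    r: float
    p: float
    p_str: str
    paired: pd.DataFrame  # columns d_a, d_b, indexed by probeset


@dataclass
class ShiftResult:
    """Distribution shift of one gene set's d-statistics vs background."""

    set_name: str
    n: int  # set members present in the background
    direction: str  # 'increased' / 'decreased' (in contrast group1)
    statistic: float
    p: float
    p_str: str
    median_set: float
    median_background: float
    method: str


def _as_d_series(result) -> pd.Series:
    if isinstance(result, SamResult):
        return result.table["d"]
    if isinstance(result, pd.Series):
        return result
    raise TypeError("expected SamResult or pandas Series of d-statistics")


def _floor_p(p: float) -> tuple[float, str]:
    if p < P_FLOOR:
        return P_FLOOR, f"<{P_FLOOR:g}"
    return float(p), f"{p:g}"


def align_by_id(result_a, result_b) -> pd.DataFrame:
    """Inner-join two d-statistic vectors on probeset ID (columns d_a, d_b)."""
    da, db = _as_d_series(result_a), _as_d_series(result_b)
    common = da.index.intersection(db.index)
    if len(common) == 0:
        raise AnalysisError("no probeset IDs in common")
    n_drop = (len(da) - len(common)) + (len(db) - len(common))
    if n_drop:
        logger.info("align_by_id: %d unmatched probesets dropped", n_drop)
    return pd.DataFrame({"d_a": da.loc[common], "d_b": db.loc[common]})


def dstat_concordance(paired: pd.DataFrame) -> ConcordanceResult:
    """Pearson r (with two-sided p) of paired d-statistics."""
    if len(paired) < 10:
        raise AnalysisError("need >=10 paired probesets")
    a = paired["d_a"].to_numpy(dtype=float)
    b = paired["d_b"].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise AnalysisError("zero variance in a d-statistic vector")
    res = stats.pearsonr(a, b)
    p, p_str = _floor_p(res.pvalue)
    return ConcordanceResult(len(paired), float(res.statistic), p, p_str, paired)


def geneset_shift_test(
    result,
    gene_set: GeneSet,
    method: str = "ranksum",
    include_members_in_background: bool = False,
    n_perm: int = 10000,
    seed: int | None = 0,
    min_size: int = MIN_SET_SIZE,
) -> ShiftResult:
    """Test whether a gene set's d-statistics are shifted vs all tested genes.

    Methods: 'ranksum' (two-sided Wilcoxon rank-sum of members vs non-members,
    the default), 'ks' (two-sample Kolmogorov-Smirnov) and 'perm' (two-sided
    permutation of the mean-d difference against >= ``n_perm`` random same-size
    sets). Direction is the sign of median(set) - median(background). By
    default set members are excluded from the background.
    """
    if method not in SHIFT_METHODS:
        raise AnalysisError(f"unknown method {method!r}; choose from {SHIFT_METHODS}")
    d = _as_d_series(result)
    members = d.index.intersection(gene_set.members)
    if len(members) < min_size:
        raise AnalysisError(
            f"set {gene_set.name!r}: only {len(members)} members present (min {min_size})"
        )
    set_d = d.loc[members].to_numpy(dtype=float)
    if include_members_in_background:
        bg_d = d.to_numpy(dtype=float)
    else:
        bg_d = d.drop(members).to_numpy(dtype=float)

    med_set = float(np.median(set_d))
    med_bg = float(np.median(bg_d)) if len(bg_d) else med_set
    direction = "increased" if med_set >= med_bg else "decreased"

    if len(bg_d) == 0:
        # degenerate: the set is the whole background
        if method == "perm":
            return ShiftResult(
                gene_set.name, len(members), direction, 0.0, 1.0, "1", med_set, med_bg, method
            )
        raise AnalysisError("set covers all genes; no complement to compare against")

    if method == "ranksum":
        res = stats.mannwhitneyu(set_d, bg_d, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "ks":
        res = stats.ks_2samp(set_d, bg_d)
        stat, p = float(res.statistic), float(res.pvalue)
    else:  # perm: random same-size sets from the full vector
        rng = np.random.default_rng(seed)
        all_d = d.to_numpy(dtype=float)
        obs = set_d.mean() - bg_d.mean()
        k, n = len(set_d), len(all_d)
        total = all_d.sum()
        perm_set_sums = np.empty(n_perm)
        chunk = max(1, int(2e7) // n)  # bound transient memory of the argsort trick
        for start in range(0, n_perm, chunk):
            stop = min(start + chunk, n_perm)
            idx = np.argsort(rng.random((stop - start, n)), axis=1)[:, :k]
            perm_set_sums[start:stop] = all_d[idx].sum(axis=1)
        perm_stats = perm_set_sums / k - (total - perm_set_sums) / (n - k)
        p = (1 + int((np.abs(perm_stats) >= abs(obs)).sum())) / (n_perm + 1)
        stat = float(obs)
    p, p_str = _floor_p(p)
    return ShiftResult(
        gene_set.name, len(members), direction, stat, p, p_str, med_set, med_bg, method
    )


def shift_density_summary(
    result,
    sets: list[GeneSet],
    grid_points: int = 256,
) -> pd.DataFrame:
    """Kernel densities of d for each set and for all genes on a common grid.

    Each curve is renormalised to integrate to 1 on the grid; the 'all_genes'
    column is the background curve. Exported as tidy TSV for plotting.
    """
    if grid_points < 2:
        raise AnalysisError("empty density grid")
    d = _as_d_series(result)
    vals = d.to_numpy(dtype=float)
    pad = 0.1 * (vals.max() - vals.min() + 1e-12)
    grid = np.linspace(vals.min() - pad, vals.max() + pad, grid_points)
    out = pd.DataFrame({"d": grid})
    out["all_genes"] = _norm_kde(vals, grid)
    for gs in sets:
        members = d.index.intersection(gs.members)
        if len(members) < 2:
            raise AnalysisError(f"set {gs.name!r} has <2 members present")
        out[gs.name] = _norm_kde(d.loc[members].to_numpy(dtype=float), grid)
    return out


def _norm_kde(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    dens = stats.gaussian_kde(x)(grid)
    return dens / np.trapezoid(dens, grid)


@dataclass
class OverlapResult:
    """Overlap of two significant-call lists on a shared probeset universe."""

    n_a: int
    n_b: int
    n_overlap: int
    frac_a_in_b: float
    frac_b_in_a: float
    p_hypergeom: float


def list_overlap(calls_a, calls_b, universe) -> OverlapResult:
    """Counts, mutual fractions and hypergeometric enrichment p of A vs B."""
    universe = set(universe)
    if not universe:
        raise AnalysisError("empty universe")
    a = set(calls_a) & universe
    b = set(calls_b) & universe
    k = len(a & b)
    n_a, n_b, big_n = len(a), len(b), len(universe)
    p = float(stats.hypergeom.sf(k - 1, big_n, n_a, n_b)) if n_a and n_b else 1.0
    return OverlapResult(
        n_a,
        n_b,
        k,
        k / n_a if n_a else 0.0,
        k / n_b if n_b else 0.0,
        p,
    )
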