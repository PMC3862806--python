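"""Moderated d-statistic differential expression with permutation FDR.

The per-gene score is the SAM-style moderated two-sample statistic

    d_i = r_i / (s_i + s0)

with r_i the difference of group means, s_i the pooled-SD-based gene scatter
and s0 an additive stabilizer ("fudge factor") chosen so that |d| is decoupled
from gene-wise variance. Significance is assessed against a permutation null:
group labels are reassigned many times, the sorted permuted d's give expected
order statistics, and symmetric delta offsets from those expectations induce
asymmetric up/down cutoffs whose false discovery rate is estimated from the
median permuted call count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, DesignError
from .ingest import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_B = 1000


@dataclass(frozen=True)
class Design:
    """A two-group contrast: ordered pair of labels plus sample -> group map.

    Samples absent from ``sample_groups`` are excluded from the contrast.
    ``r_i`` (and hence ``d_i``) is mean(group1) - mean(group2), so positive d
    means increased expression in ``contrast[0]``.
    """

    contrast: tuple[str, str]
    sample_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        g1, g2 = self.contrast
        if g1 == g2:
            raise DesignError("contrast groups must differ")
        counts = {g1: 0, g2: 0}
        for s, g in self.sample_groups.items():
            if g not in counts:
                raise DesignError(f"sample {s!r} mapped to unknown group {g!r}")
            counts[g] += 1
        for g, c in counts.items():
            if c < 2:
                raise DesignError(f"group {g!r} has {c} samples; need >= 2")

    @classmethod
    def from_annotations(
        cls,
        matrix: ExpressionMatrix,
        group1: str,
        group2: str,
        by: str = "phenotype",
        condition: str | None = None,
        labels: tuple[str, str] | None = None,
    ) -> "Design":
        """Build a contrast from sample annotations.

        ``by`` names the annotation column whose values ``group1``/``group2``
        define the groups. With ``condition`` set, samples are restricted to
        that condition; otherwise conditions are merged into the phenotype
        groups (label merging, e.g. AU-act = AU-S u AU-NS). ``labels``
        optionally renames the contrast (e.g. ("AU-act", "AI-act")).
        """
        ann = matrix.samples
        if by not in ann.columns:
            raise DesignError(f"annotation column {by!r} missing")
        mask = ann[by].isin([group1, group2])
        if condition is not None:
            if "condition" not in ann.columns:
                raise DesignError("annotation column 'condition' missing")
            mask &= ann["condition"] == condition
        lab1, lab2 = labels if labels is not None else (group1, group2)
        groups = {
            s: (lab1 if ann.loc[s, by] == group1 else lab2)
            for s in ann.index[mask]
        }
        return cls((lab1, lab2), groups)

    def group_samples(self) -> tuple[list[str], list[str]]:
        g1, g2 = self.contrast
        s1 = [s for s, g in self.sample_groups.items() if g == g1]
        s2 = [s for s, g in self.sample_groups.items() if g == g2]
        return s1, s2


@dataclass
class PermutationNull:
    """Sorted permuted d's (B x genes) and the expected order statistics."""

    d_sorted: np.ndarray  # each row one permutation, ascending within row
    dbar: np.ndarray  # mean over permutations of each order statistic
    n_assignments: int  # distinct label assignments available
    exhaustive: bool
    s0: float


@dataclass
class SamResult:
    """Full output of one moderated d-statistic analysis."""

    table: pd.DataFrame  # index probeset_id; columns r, s, d
    s0: float
    B: int
    dbar: np.ndarray
    delta_table: pd.DataFrame
    calls: dict[float, pd.DataFrame] = field(default_factory=dict)
    design: Design | None = None

    @property
    def d(self) -> pd.Series:
        return self.table["d"]

    def called_ids(self, fdr: float, direction: str | None = None) -> list[str]:
        calls = self.calls[fdr]
        mask = calls["called"]
        if direction is not None:
            mask &= calls["direction"] == direction
        return list(calls.index[mask])

    def summary(self) -> dict:
        out = {
            "n_genes": int(len(self.table)),
            "s0": float(self.s0),
            "n_permutations": int(self.B),
        }
        for fdr, calls in self.calls.items():
            n_inc = int(((calls["direction"] == "increased") & calls["called"]).sum())
            n_dec = int(((calls["direction"] == "decreased") & calls["called"]).sum())
            out[f"n_called_fdr_{fdr:g}"] = n_inc + n_dec
            out[f"n_increased_fdr_{fdr:g}"] = n_inc
            out[f"n_decreased_fdr_{fdr:g}"] = n_dec
        return out


def _group_arrays(matrix: ExpressionMatrix, design: Design) -> tuple[np.ndarray, np.ndarray]:
    s1, s2 = design.group_samples()
    missing = [s for s in (*s1, *s2) if s not in matrix.sample_ids]
    if missing:
        raise DesignError(f"design samples absent from matrix: {missing}")
    return (
        matrix.values[s1].to_numpy(dtype=float),
        matrix.values[s2].to_numpy(dtype=float),
    )


def _pooled_stats(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    r = m1 - m2
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return r, s


def compute_d(
    matrix: ExpressionMatrix, design: Design, s0: float = 0.0
) -> pd.DataFrame:
    """Per-gene mean difference r, gene scatter s and moderated d = r/(s+s0).

    With s0 = 0, d is the classical pooled two-sample t-statistic. Zero
    within-group variance with s0 = 0 yields +/-inf d with a warning.
    """
    x1, x2 = _group_arrays(matrix, design)
    r, s = _pooled_stats(x1, x2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / (s + s0)
    zero_div = (s + s0) == 0
    if zero_div.any():
        warnings.warn(
            f"{int(zero_div.sum())} genes with zero scatter and s0=0; d set to +/-inf"
        )
        d = np.where(zero_div, np.sign(r) * np.inf, d)
        d = np.where(zero_div & (r == 0), 0.0, d)
    return pd.DataFrame({"r": r, "s": s, "d": d}, index=matrix.probeset_ids)


def choose_s0(
    r: np.ndarray | pd.Series,
    s: np.ndarray | pd.Series,
    candidate_percentiles: Sequence[float] | None = None,
    n_windows: int = 100,
) -> float:
    """Select the fudge factor s0 that flattens |d| dispersion across s.

    Candidates are percentiles (default 0, 5, ..., 100) of the gene scatter s.
    For each candidate, genes are split into ``n_windows`` quantile windows of
    s and the median absolute deviation (MAD) of d is computed per window; the
    candidate minimizing the coefficient of variation of the window MADs wins,
    ties going to the smaller s0.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if s.std() == 0:
        warnings.warn("choose_s0: degenerate gene scatter (all equal); s0 = 0")
        return 0.0
    if candidate_percentiles is None:
        candidate_percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(s, candidate_percentiles)
    n = len(s)
    n_windows = min(n_windows, max(2, n // 10))
    order = np.argsort(s, kind="stable")
    window = np.empty(n, dtype=int)
    window[order] = np.minimum((np.arange(n) * n_windows) // n, n_windows - 1)
    best_s0, best_cv = None, np.inf
    for cand in np.sort(candidates):
        d = r / (s + cand)
        mads = np.array(
            [_mad(d[window == w]) for w in range(n_windows)]
        )
        mean = mads.mean()
        cv = np.inf if mean == 0 else mads.std(ddof=1) / mean
        if cv < best_cv:  # strict: ties keep the smaller candidate
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x)))) if len(x) else 0.0


def _enumerate_assignments(n: int, n1: int) -> np.ndarray:
    return np.array(list(combinations(range(n), n1)), dtype=int)


def _sample_assignments(
    n: int, n1: int, B: int, rng: np.random.Generator, total: int
) -> np.ndarray:
    if B <= total:
        # uniform without replacement over the assignment space
        seen: set[tuple[int, ...]] = set()
        while len(seen) < B:
            seen.add(tuple(sorted(rng.choice(n, size=n1, replace=False).tolist())))
        return np.array(sorted(seen), dtype=int)
    # more draws than distinct assignments: fall back to with-replacement
    return np.array(
        [sorted(rng.choice(n, size=n1, replace=False).tolist()) for _ in range(B)],
        dtype=int,
    )


def permute_null(
    matrix: ExpressionMatrix,
    design: Design,
    B: int = DEFAULT_B,
    seed: int | None = 0,
    s0: float = 0.0,
    exhaustive: bool | None = None,
) -> PermutationNull:
    """Permutation null of d by reassigning group labels.

    All C(n, n1) distinct assignments are enumerated when their count is <= B
    (or when ``exhaustive=True``); otherwise B assignments are sampled
    uniformly without replacement (with replacement only if B exceeds the
    assignment space and sampling is forced with ``exhaustive=False``).
    Deterministic given ``seed``.
    """
    if B < 1:
        raise AnalysisError("B must be >= 1")
    x1, x2 = _group_arrays(matrix, design)
    x = np.hstack([x1, x2])
    n1, n = x1.shape[1], x.shape[1]
    total = math.comb(n, n1)
    if exhaustive is None:
        exhaustive = total <= B
    if exhaustive:
        assign = _enumerate_assignments(n, n1)
    else:
        rng = np.random.default_rng(seed)
        assign = _sample_assignments(n, n1, B, rng, total)

    ind = np.zeros((n, len(assign)))
    ind[assign.T, np.arange(len(assign))[None, :]] = 1.0
    d = _d_for_assignments(x, ind, n1, s0)
    d_sorted = np.sort(d, axis=0).T  # B x genes, ascending
    dbar = d_sorted.mean(axis=0)
    return PermutationNull(d_sorted, dbar, total, bool(exhaustive), s0)


def _d_for_assignments(
    x: np.ndarray, ind: np.ndarray, n1: int, s0: float
) -> np.ndarray:
    """d for every column of the group-1 indicator matrix ``ind`` (n x B)."""
    n = x.shape[1]
    n2 = n - n1
    tot = x.sum(axis=1, keepdims=True)
    tot2 = (x**2).sum(axis=1, keepdims=True)
    s1 = x @ ind
    q1 = (x**2) @ ind
    s2, q2 = tot - s1, tot2 - q1
    ss1 = np.clip(q1 - s1**2 / n1, 0.0, None)
    ss2 = np.clip(q2 - s2**2 / n2, 0.0, None)
    r = s1 / n1 - s2 / n2
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / (s + s0)
    return np.nan_to_num(d, nan=0.0, posinf=np.inf, neginf=-np.inf)


def estimate_fdr_table(
    d: pd.Series | np.ndarray,
    null: PermutationNull,
    deltas: Sequence[float] | None = None,
    pi0: float = 1.0,
) -> pd.DataFrame:
    """Delta table: symmetric offsets -> asymmetric cutoffs, calls and FDR.

    For each delta, genes are called up where the sorted observed d exceeds its
    expected order statistic by more than delta (cut_up = smallest such d) and
    down symmetrically (cut_low = largest such d). Estimated FDR is pi0 times
    the median over permutations of the permuted-d count beyond (cut_low,
    cut_up), divided by the observed call count, capped at 1; zero calls give
    NaN. The FDR column is monotone-regularised (non-increasing in delta).
    """
    d = np.asarray(d, dtype=float)
    d_sorted = np.sort(d)
    if len(d_sorted) != len(null.dbar):
        raise AnalysisError("observed d and permutation null differ in gene count")
    dev = d_sorted - null.dbar
    if deltas is None:
        hi = float(np.abs(dev).max()) if len(dev) else 1.0
        deltas = np.linspace(0.0, hi + 1e-9, 101)
    rows = []
    for delta in deltas:
        cut_up, cut_low, n_called = _cuts_at_delta(d_sorted, dev, delta)
        if n_called == 0:
            rows.append((delta, cut_low, cut_up, 0, np.nan, 0, np.nan))
            continue
        false = (
            (null.d_sorted >= cut_up).sum(axis=1)
            + (null.d_sorted <= cut_low).sum(axis=1)
        )
        med_false = float(np.median(false))
        fdr = min(1.0, pi0 * med_false / n_called)
        rows.append((delta, cut_low, cut_up, n_called, med_false, int(false.max()), fdr))
    table = pd.DataFrame(
        rows,
        columns=[
            "delta", "cut_low", "cut_up", "n_called", "median_false", "max_false", "fdr",
        ],
    )
    # enforce monotone non-increasing FDR in delta: a smaller delta can never
    # have a lower estimate than any larger one (conservative; only raises)
    vals = table["fdr"].to_numpy()
    mask = ~np.isnan(vals)
    vals[mask] = np.maximum.accumulate(vals[mask][::-1])[::-1]
    table["fdr"] = vals
    return table


def _cuts_at_delta(
    d_sorted: np.ndarray, dev: np.ndarray, delta: float
) -> tuple[float, float, int]:
    up = dev > delta
    low = -dev > delta
    cut_up = float(d_sorted[up].min()) if up.any() else np.inf
    cut_low = float(d_sorted[low].max()) if low.any() else -np.inf
    n_called = int(((d_sorted >= cut_up) | (d_sorted <= cut_low)).sum())
    return cut_up, cut_low, n_called


def call_significant(
    delta_table: pd.DataFrame,
    d: pd.Series,
    target_fdr: float,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Per-gene significance flags at the smallest delta meeting ``target_fdr``.

    Returns (calls, chosen_row); calls has boolean ``called`` and ``direction``
    ('increased'/'decreased' in group1, '' if not called). No delta meeting the
    target yields zero calls and chosen_row None. A target of exactly 0 demands
    more than a zero *median* permuted false count: no permutation at all may
    produce a call beyond the cutoffs.
    """
    if delta_table.empty:
        raise AnalysisError("empty delta table")
    keep = delta_table["fdr"].notna() & (delta_table["fdr"] <= target_fdr)
    if target_fdr == 0 and "max_false" in delta_table.columns:
        keep &= delta_table["max_false"] == 0
    ok = delta_table[keep]
    calls = pd.DataFrame(
        {"called": False, "direction": ""}, index=d.index, dtype=object
    )
    calls["called"] = calls["called"].astype(bool)
    if ok.empty:
        logger.info("no delta meets FDR %.3g; zero calls", target_fdr)
        return calls, None
    row = ok.iloc[0]  # smallest delta (table is in ascending delta order)
    up = d >= row["cut_up"]
    down = d <= row["cut_low"]
    calls.loc[up, ["called", "direction"]] = [True, "increased"]
    calls.loc[down, ["called", "direction"]] = [True, "decreased"]
    calls["called"] = calls["called"].astype(bool)
    calls["direction"] = calls["direction"].astype(str)
    return calls, row


def sam_analysis(
    matrix: ExpressionMatrix,
    design: Design,
    target_fdrs: Sequence[float] = (0.05,),
    B: int = DEFAULT_B,
    seed: int | None = 0,
    s0: float | None = None,
    deltas: Sequence[float] | None = None,
    pi0: float = 1.0,
    exhaustive: bool | None = None,
) -> SamResult:
    """End-to-end moderated d analysis: s0 selection, null, FDR table, calls.

    ``s0=None`` (default) selects the fudge factor automatically from the
    observed r/s via :func:`choose_s0`.
    """
    base = compute_d(matrix, design, s0=0.0)
    if s0 is None:
        s0 = choose_s0(base["r"].to_numpy(), base["s"].to_numpy())
    table = compute_d(matrix, design, s0=s0)
    null = permute_null(matrix, design, B=B, seed=seed, s0=s0, exhaustive=exhaustive)
    delta_table = estimate_fdr_table(table["d"], null, deltas=deltas, pi0=pi0)
    result = SamResult(
        table=table,
        s0=float(s0),
        B=null.d_sorted.shape[0],
        dbar=null.dbar,
        delta_table=delta_table,
        design=design,
    )
    for fdr in target_fdrs:
        calls, _ = call_significant(delta_table, table["d"], fdr)
        result.calls[fdr] = calls
    return result


def dstat_density(
    result: SamResult, grid_points: int = 512
) -> pd.DataFrame:
    """Observed vs expected (permutation) d-statistic densities on one grid.

    Both curves are kernel-density estimates renormalized to integrate to 1 on
    the grid, the standard display for judging how far the observed
    distribution's tails escape the permutation null.
    """
    from scipy.stats import gaussian_kde

    d = result.table["d"].to_numpy()
    expected = result.dbar
    lo = min(d.min(), expected.min())
    hi = max(d.max(), expected.max())
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    obs = gaussian_kde(d)(grid)
    exp = gaussian_kde(expected)(grid)
    obs /= np.trapezoid(obs, grid)
    exp /= np.trapezoid(exp, grid)
    return pd.DataFrame({"d": grid, "observed": obs, "expected": exp})
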