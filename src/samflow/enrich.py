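"""Over-representation analysis of significant gene lists.

Functional annotation groups are supplied as GMT gene sets; each group is
tested for over-representation in a query list by the upper-tail
hypergeometric test against the analysis background (all probesets surviving
the low-expression filter), with Bonferroni correction over the groups that
actually overlap the universe and a significance flag at corrected p < 0.05.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .genesets import GeneSet

BONFERRONI_ALPHA = 0.05

RESULT_COLUMNS = [
    "group",
    "k_overlap",
    "m_group",
    "n_query",
    "N_universe",
    "p_hypergeom",
    "p_bonferroni",
    "significant",
]


def ora_test(
    query: Iterable[str],
    groups: Sequence[GeneSet],
    universe: Iterable[str],
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotation group.

    Groups are intersected with the universe before testing; groups with no
    members in the universe are dropped and do not count toward the Bonferroni
    factor. The query must be a subset of the universe. Rows are sorted by
    corrected p, then group name.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise AnalysisError("empty universe")
    if not query:
        raise AnalysisError("empty query")
    stray = query - universe
    if stray:
        raise AnalysisError(
            f"{len(stray)} query IDs outside the universe, e.g. {sorted(stray)[:3]}"
        )
    n, big_n = len(query), len(universe)
    rows = []
    for gs in groups:
        members = gs.members & universe
        m = len(members)
        if m == 0:
            continue
        k = len(members & query)
        # upper tail including the observed count
        p = float(stats.hypergeom.sf(k - 1, big_n, m, n))
        rows.append((gs.name, k, m, n, big_n, p))
    n_tested = len(rows)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS[:6])
    out["p_bonferroni"] = (out["p_hypergeom"] * n_tested).clip(upper=1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values(
        ["p_bonferroni", "group"], kind="stable", ignore_index=True
    )


def split_by_direction(calls: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Partition called probesets into (increased, decreased) query lists.

    ``calls`` is a per-gene frame with boolean ``called`` and ``direction``
    columns as produced by the d-statistic significance caller.
    """
    for col in ("called", "direction"):
        if col not in calls.columns:
            raise AnalysisError(f"calls frame missing column {col!r}")
    called = calls[calls["called"].astype(bool)]
    up = list(called.index[called["direction"] == "increased"])
    down = list(called.index[called["direction"] == "decreased"])
    return up, down
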