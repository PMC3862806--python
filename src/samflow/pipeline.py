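"""End-to-end synthetic-cohort analysis: simulate -> QC -> filter -> DE -> compare.

One call reproduces the whole study workflow on generated data: cohort
simulation, outlier-array QC, quantile normalization, empirical low-intensity
filtering, moderated d-statistic analyses (combined phenotypes at one FDR,
per-condition contrasts at a looser FDR), correlation-distance MDS, S-vs-NS
d-statistic concordance, gene-set shift tests against the planted truth, and
over-representation of the called genes. All outputs are plain TSV/JSON and
byte-identical across runs with the same config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossmap, enrich, ingest, ordination, samstat
from .genesets import GeneSet, write_gmt
from .synthio import SimConfig, generate_cohort, write_truth


def _phenotypes(config: SimConfig) -> tuple[str, str]:
    phenos = sorted({g.split("-")[0] for g in config.group_sizes})
    if len(phenos) != 2:
        raise ValueError("pipeline expects exactly two phenotypes")
    # put the DE-target phenotype first so planted effects read as 'increased'
    if config.de_phenotype in phenos:
        phenos.remove(config.de_phenotype)
        phenos.insert(0, config.de_phenotype)
    return phenos[0], phenos[1]


def truth_gene_sets(truth: pd.DataFrame, seed: int, n_random: int = 3, random_size: int = 100) -> list[GeneSet]:
    """Annotation groups derived from the simulation truth.

    The planted up- and down-shifted sets plus a few random expressed-gene
    sets, giving the shift tests and the over-representation step both signal
    and null groups to work with.
    """
    rng = np.random.default_rng(seed)
    up = truth.loc[truth["true_effect"] > 0, "probeset_id"]
    down = truth.loc[truth["true_effect"] < 0, "probeset_id"]
    expressed = truth.loc[~truth["is_low"], "probeset_id"].to_numpy()
    sets = []
    if len(up) >= crossmap.MIN_SET_SIZE:
        sets.append(GeneSet("planted_up", frozenset(up), "planted up-shifted genes"))
    if len(down) >= crossmap.MIN_SET_SIZE:
        sets.append(GeneSet("planted_down", frozenset(down), "planted down-shifted genes"))
    for i in range(n_random):
        size = min(random_size, len(expressed))
        members = rng.choice(expressed, size=size, replace=False)
        sets.append(GeneSet(f"random_{i + 1}", frozenset(members), "random expressed genes"))
    return sets


def run_pipeline(
    config: SimConfig,
    out_dir,
    fdr: float = 0.05,
    fdr_within: float = 0.1,
    B: int = samstat.DEFAULT_B,
    cutoff: float | str = "auto",
    shift_method: str = "ranksum",
) -> dict:
    """Run the full analysis; writes TSV/JSON artifacts and returns the summary.

    ``cutoff='auto'`` detects the low-expression limit from the bimodal
    intensity distribution (falling back to log2 = 4); a float applies that
    limit directly. All randomness derives from ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    # --- simulate ---------------------------------------------------------
    matrix, truth = generate_cohort(config)
    matrix.to_tsv(out / "matrix.tsv")
    matrix.sample_sheet_to_tsv(out / "samples.tsv")
    write_truth(truth, out / "truth.tsv")

    # --- QC, normalize, filter -------------------------------------------
    qc = ingest.detect_outlier_arrays(matrix)
    if qc.flagged_outliers:
        keep = [s for s in matrix.sample_ids if s not in set(qc.flagged_outliers)]
        matrix = matrix.subset_samples(keep)
    matrix = ingest.quantile_normalize(matrix)
    cutoff_val = (
        ingest.detect_low_cutoff(matrix) if cutoff == "auto" else float(cutoff)
    )
    filtered = ingest.filter_low_expression(matrix, cutoff_val)
    qc.cutoff_used = float(cutoff_val)
    qc.n_genes_retained = int(filtered.n_genes)
    (out / "qc_report.json").write_text(
        json.dumps(qc.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    p1, p2 = _phenotypes(config)

    # --- differential expression -----------------------------------------
    design_act = samstat.Design.from_annotations(
        filtered, p1, p2, labels=(f"{p1}-act", f"{p2}-act")
    )
    sam_act = samstat.sam_analysis(
        filtered, design_act, target_fdrs=(fdr,), B=B, seed=seed
    )
    _write_sam(sam_act, fdr, out, "sam_act")

    conditions = sorted({g.split("-", 1)[1] for g in config.group_sizes if "-" in g})
    sam_by_condition: dict[str, samstat.SamResult] = {}
    for cond in conditions:
        design_c = samstat.Design.from_annotations(
            filtered, p1, p2, condition=cond,
            labels=(f"{p1}-{cond}", f"{p2}-{cond}"),
        )
        res = samstat.sam_analysis(
            filtered, design_c, target_fdrs=(fdr_within,), B=B, seed=seed + 1
        )
        sam_by_condition[cond] = res
        _write_sam(res, fdr_within, out, f"sam_{cond}")

    # --- ordination -------------------------------------------------------
    dist = ordination.correlation_distance(filtered)
    mds = ordination.classical_mds(dist, k=2)
    ordination.embedding_to_tsv(mds, filtered, out / "mds_coords.tsv")
    pca = ordination.pca_scores(filtered, k=2)
    ordination.embedding_to_tsv(pca, filtered, out / "pca_coords.tsv")

    # --- cross-comparison and gene sets ----------------------------------
    summary: dict = {
        "config_seed": seed,
        "n_genes_simulated": int(config.n_genes),
        "n_arrays": int(sum(config.group_sizes.values())),
        "flagged_outliers": list(qc.flagged_outliers),
        "low_cutoff": float(cutoff_val),
        "n_genes_retained": int(filtered.n_genes),
        "sam_act": sam_act.summary(),
    }
    if len(conditions) >= 2:
        paired = crossmap.align_by_id(
            sam_by_condition[conditions[0]], sam_by_condition[conditions[1]]
        )
        conc = crossmap.dstat_concordance(paired)
        paired.rename_axis("probeset_id").to_csv(out / "concordance_pairs.tsv", sep="\t")
        summary["condition_concordance"] = {
            "conditions": conditions[:2],
            "n_paired": conc.n_paired,
            "r": conc.r,
            "p": conc.p_str,
        }

    sets = truth_gene_sets(truth, seed=seed + 2)
    write_gmt(sets, out / "gene_sets.gmt")
    shift_rows = []
    for gs in sets:
        try:
            res = crossmap.geneset_shift_test(
                sam_act, gs, method=shift_method, seed=seed + 3
            )
        except Exception:  # tiny planted sets can fall below the size floor
            continue
        shift_rows.append(
            (res.set_name, res.n, res.direction, res.statistic, res.p, res.p_str)
        )
    shift_df = pd.DataFrame(
        shift_rows, columns=["set", "n", "direction", "statistic", "p", "p_str"]
    )
    shift_df.to_csv(out / "shift_tests.tsv", sep="\t", index=False)
    summary["shift_tests"] = shift_rows and {
        r[0]: {"n": r[1], "direction": r[2], "p": r[5]} for r in shift_rows
    } or {}
    density = crossmap.shift_density_summary(sam_act, [s for s in sets if s.name.startswith("planted")])
    density.to_csv(out / "shift_densities.tsv", sep="\t", index=False)

    # --- enrichment -------------------------------------------------------
    up, down = enrich.split_by_direction(sam_act.calls[fdr])
    universe = list(filtered.probeset_ids)
    if up:
        ora = enrich.ora_test(up, sets, universe)
        ora.to_csv(out / "enrichment_increased.tsv", sep="\t", index=False)
        summary["enrichment_increased"] = {
            "n_groups_tested": int(len(ora)),
            "n_significant": int(ora["significant"].sum()),
        }
    if down:
        ora_dn = enrich.ora_test(down, sets, universe)
        ora_dn.to_csv(out / "enrichment_decreased.tsv", sep="\t", index=False)
        summary["enrichment_decreased"] = {
            "n_groups_tested": int(len(ora_dn)),
            "n_significant": int(ora_dn["significant"].sum()),
        }

    # --- recovery vs truth ------------------------------------------------
    truth_idx = truth.set_index("probeset_id")
    called = set(sam_act.called_ids(fdr))
    de_ids = set(truth_idx.index[truth_idx["is_de"]])
    retained = set(filtered.probeset_ids)
    de_retained = de_ids & retained
    tp = len(called & de_ids)
    summary["recovery"] = {
        "n_called": len(called),
        "n_planted_retained": len(de_retained),
        "sensitivity": tp / len(de_retained) if de_retained else float("nan"),
        "empirical_fdr": (len(called) - tp) / len(called) if called else float("nan"),
    }

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _write_sam(result: samstat.SamResult, fdr: float, out: Path, stem: str) -> None:
    table = result.table.copy()
    calls = result.calls[fdr]
    table["called"] = calls["called"]
    table["direction"] = calls["direction"]
    table.rename_axis("probeset_id").to_csv(out / f"{stem}_genes.tsv", sep="\t")
    result.delta_table.to_csv(out / f"{stem}_delta_table.tsv", sep="\t", index=False)
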