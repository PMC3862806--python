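"""Cross-dataset comparisons on the d-statistic scale.

Concordance of the S and NS contrasts within the activated cohort, the
activated-vs-basal comparison across the paired datasets, gene-set
distribution-shift tests of the planted sets, and overlap of significant
lists across datasets — all by probeset identifier.
"""

import importlib
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from samflow import (
    Design,
    GeneSet,
    align_by_id,
    dstat_concordance,
    geneset_shift_test,
    list_overlap,
    read_matrix,
    read_sample_sheet,
    read_truth,
    sam_analysis,
    shift_density_summary,
)


def load_d(stem):
    return pd.read_csv(cfg.RESULTS / f"sam_{stem}_genes.tsv", sep="\t",
                       index_col="probeset_id")


def sam_for(prefix, seed):
    m = read_sample_sheet(
        cfg.DATA / f"{prefix}_samples.tsv",
        read_matrix(cfg.DATA / f"{prefix}_matrix.tsv"),
    )
    design = Design.from_annotations(m, "AU", "AI")
    return sam_analysis(m, design, target_fdrs=(0.05,), B=cfg.B_PERMUTATIONS, seed=seed)


def main() -> None:
    out = {}

    # S vs NS concordance within the activated cohort
    d_s, d_ns = load_d("S"), load_d("NS")
    conc = dstat_concordance(align_by_id(d_s["d"], d_ns["d"]))
    out["s_vs_ns"] = {"n": conc.n_paired, "r": round(conc.r, 4), "p": conc.p_str}
    print(f"S vs NS d-statistic concordance: r={conc.r:.3f} (p={conc.p_str}, "
          f"N={conc.n_paired} probesets)")

    # activated vs basal across the independently simulated pair
    sam_act = sam_for("pair_act", cfg.SEED + 10)
    sam_basal = sam_for("pair_basal", cfg.SEED + 11)
    conc2 = dstat_concordance(align_by_id(sam_act, sam_basal))
    out["act_vs_basal"] = {"n": conc2.n_paired, "r": round(conc2.r, 4), "p": conc2.p_str}
    print(f"activated vs basal concordance (share="
          f"{cfg.PAIRED.cross_dataset_share:g}): r={conc2.r:.3f}")

    # shift tests: do the basal dataset's planted sets move in the activated data?
    basal_truth = read_truth(cfg.DATA / "pair_basal_truth.tsv")
    sets = {
        "basal_up": GeneSet(
            "basal_up",
            basal_truth.loc[basal_truth["true_effect"] > 0, "probeset_id"],
            "genes planted up in the basal dataset",
        ),
        "basal_down": GeneSet(
            "basal_down",
            basal_truth.loc[basal_truth["true_effect"] < 0, "probeset_id"],
            "genes planted down in the basal dataset",
        ),
    }
    shift_rows = []
    for gs in sets.values():
        res = geneset_shift_test(sam_act, gs, seed=cfg.SEED)
        shift_rows.append((res.set_name, res.n, res.direction, res.p_str))
        print(f"shift test {res.set_name}: N={res.n}, {res.direction} in AU-act, p={res.p_str}")
    pd.DataFrame(shift_rows, columns=["set", "n", "direction", "p"]).to_csv(
        cfg.RESULTS / "shift_tests.tsv", sep="\t", index=False
    )
    shift_density_summary(sam_act, list(sets.values())).to_csv(
        cfg.RESULTS / "shift_densities.tsv", sep="\t", index=False
    )

    # overlap of significant lists across the paired datasets
    calls_a = sam_act.called_ids(0.05, "increased")
    calls_b = sam_basal.called_ids(0.05, "increased")
    universe = sam_act.table.index.intersection(sam_basal.table.index)
    ov = list_overlap(calls_a, calls_b, universe)
    out["increased_list_overlap"] = {
        "n_act": ov.n_a, "n_basal": ov.n_b, "n_overlap": ov.n_overlap,
        "frac_act_in_basal": round(ov.frac_a_in_b, 3),
        "p_hypergeom": float(f"{ov.p_hypergeom:.3g}"),
    }
    print(f"increased-call overlap: {ov.n_overlap}/{ov.n_a} activated calls also "
          f"basal-increased ({ov.frac_a_in_b:.0%}; hypergeometric p={ov.p_hypergeom:.2g})")

    (cfg.RESULTS / "cross_dataset.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n"
    )


if __name__ == "__main__":
    main()
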