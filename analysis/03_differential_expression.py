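"""Moderated d-statistic contrasts: per-condition and combined phenotypes.

Runs AU-S v AI-S and AU-NS v AI-NS at FDR 0.1 (small subgroups) and the
combined AU-act v AI-act contrast at FDR 0.05, mirroring the looser threshold
within conditions and the stricter one once conditions are merged for power.
Writes per-gene tables, delta tables and density summaries.
"""

import importlib
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from samflow import Design, dstat_density, read_matrix, read_sample_sheet, sam_analysis


def run_contrast(matrix, condition, fdr, seed):
    label = condition or "act"
    design = Design.from_annotations(
        matrix, "AU", "AI", condition=condition,
        labels=(f"AU-{label}", f"AI-{label}"),
    )
    res = sam_analysis(
        matrix, design, target_fdrs=(fdr,), B=cfg.B_PERMUTATIONS, seed=seed
    )
    table = res.table.copy()
    table["called"] = res.calls[fdr]["called"]
    table["direction"] = res.calls[fdr]["direction"]
    table.rename_axis("probeset_id").to_csv(
        cfg.RESULTS / f"sam_{label}_genes.tsv", sep="\t"
    )
    res.delta_table.to_csv(cfg.RESULTS / f"sam_{label}_delta.tsv", sep="\t", index=False)
    dstat_density(res).to_csv(cfg.RESULTS / f"sam_{label}_density.tsv", sep="\t", index=False)
    s = res.summary()
    print(
        f"{design.contrast[0]} v {design.contrast[1]} (FDR {fdr:g}): "
        f"{s[f'n_called_fdr_{fdr:g}']} probesets called "
        f"({s[f'n_increased_fdr_{fdr:g}']} increased in AU, s0={res.s0:.4f})"
    )
    return s


def main() -> None:
    matrix = read_sample_sheet(
        cfg.DATA / "activated_samples.tsv",
        read_matrix(cfg.DATA / "activated_filtered.tsv"),
    )
    summary = {
        "S": run_contrast(matrix, "S", 0.1, cfg.SEED),
        "NS": run_contrast(matrix, "NS", 0.1, cfg.SEED + 1),
        "act": run_contrast(matrix, None, 0.05, cfg.SEED + 2),
    }
    (cfg.RESULTS / "de_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )


if __name__ == "__main__":
    main()
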