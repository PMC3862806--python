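"""Simulate the activated cohort and its paired basal dataset.

Writes the expression matrices, sample sheets and ground-truth tables that
the downstream scripts consume.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from samflow import generate_cohort, generate_paired_datasets, write_truth


def main() -> None:
    cfg.DATA.mkdir(parents=True, exist_ok=True)

    matrix, truth = generate_cohort(cfg.COHORT)
    matrix.to_tsv(cfg.DATA / "activated_matrix.tsv")
    matrix.sample_sheet_to_tsv(cfg.DATA / "activated_samples.tsv")
    write_truth(truth, cfg.DATA / "activated_truth.tsv")
    print(
        f"activated cohort: {matrix.n_genes} probesets x {matrix.n_samples} arrays, "
        f"{int(truth['is_de'].sum())} DE genes planted, "
        f"{truth['is_low'].mean():.0%} in the low-intensity mode"
    )

    (act, act_truth), (basal, basal_truth), shared = generate_paired_datasets(cfg.PAIRED)
    for name, (m, t) in {"pair_act": (act, act_truth), "pair_basal": (basal, basal_truth)}.items():
        m.to_tsv(cfg.DATA / f"{name}_matrix.tsv")
        m.sample_sheet_to_tsv(cfg.DATA / f"{name}_samples.tsv")
        write_truth(t, cfg.DATA / f"{name}_truth.tsv")
    print(
        f"paired datasets: {len(shared)} DE effects forced common "
        f"(share={cfg.PAIRED.cross_dataset_share:g} of {cfg.PAIRED.n_de})"
    )


if __name__ == "__main__":
    main()
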