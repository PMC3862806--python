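"""Over-representation of the called genes in truth-derived annotation groups.

Genes increased in AU-act are tested separately from those decreased, against
annotation groups built from the simulation truth (the planted sets plus
random null groups), with Bonferroni-corrected hypergeometric p-values.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from samflow import ora_test, read_truth, split_by_direction, write_gmt
from samflow.pipeline import truth_gene_sets


def main() -> None:
    genes = pd.read_csv(cfg.RESULTS / "sam_act_genes.tsv", sep="\t",
                        index_col="probeset_id")
    truth = read_truth(cfg.DATA / "activated_truth.tsv")
    groups = truth_gene_sets(truth, seed=cfg.SEED + 20)
    write_gmt(groups, cfg.RESULTS / "annotation_groups.gmt")

    universe = list(genes.index)
    up, down = split_by_direction(genes[["called", "direction"]])
    for name, query in (("increased", up), ("decreased", down)):
        if not query:
            print(f"no {name} calls; skipping")
            continue
        res = ora_test(query, groups, universe)
        res.to_csv(cfg.RESULTS / f"enrichment_{name}.tsv", sep="\t", index=False)
        sig = res[res["significant"]]
        print(f"{name} in AU-act ({len(query)} probesets): "
              f"{len(sig)}/{len(res)} groups at Bonferroni p<0.05 "
              f"({', '.join(sig['group']) or 'none'})")


if __name__ == "__main__":
    main()
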