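"""QC, quantile-normalize and low-intensity filter the activated cohort.

Flags outlier arrays from median inter-array correlations, normalizes, finds
the empirical low-expression cutoff from the bimodal intensity density, and
writes the filtered matrix used by every downstream analysis.
"""

import importlib
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from samflow import (
    detect_low_cutoff,
    detect_outlier_arrays,
    filter_low_expression,
    quantile_normalize,
    read_matrix,
    read_sample_sheet,
)


def main() -> None:
    matrix = read_sample_sheet(
        cfg.DATA / "activated_samples.tsv",
        read_matrix(cfg.DATA / "activated_matrix.tsv"),
    )
    qc = detect_outlier_arrays(matrix)
    if qc.flagged_outliers:
        matrix = matrix.subset_samples(
            [s for s in matrix.sample_ids if s not in set(qc.flagged_outliers)]
        )
        print(f"excluded {len(qc.flagged_outliers)} outlier array(s): {qc.flagged_outliers}")
    else:
        print("no outlier arrays flagged")

    matrix = quantile_normalize(matrix)
    cutoff = detect_low_cutoff(matrix)
    filtered = filter_low_expression(matrix, cutoff)
    qc.cutoff_used = float(cutoff)
    qc.n_genes_retained = int(filtered.n_genes)
    print(
        f"low-expression cutoff log2={cutoff:.3f}: retained "
        f"{filtered.n_genes} of {matrix.n_genes} probesets"
    )

    filtered.to_tsv(cfg.DATA / "activated_filtered.tsv")
    (cfg.RESULTS / "qc_report.json").write_text(
        json.dumps(qc.to_dict(), indent=2, sort_keys=True) + "\n"
    )


if __name__ == "__main__":
    main()
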