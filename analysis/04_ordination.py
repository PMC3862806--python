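"""Global expression structure: 1-r MDS and PCA of the filtered arrays.

Each array becomes a point in 2-D; phenotype clustering shows up as smaller
within-group than between-group distances.
"""

import importlib
import sys
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from samflow import classical_mds, correlation_distance, pca_scores, read_matrix, read_sample_sheet
from samflow.ordination import embedding_to_tsv


def main() -> None:
    matrix = read_sample_sheet(
        cfg.DATA / "activated_samples.tsv",
        read_matrix(cfg.DATA / "activated_filtered.tsv"),
    )
    mds = classical_mds(correlation_distance(matrix), k=2)
    embedding_to_tsv(mds, matrix, cfg.RESULTS / "mds_coords.tsv")
    pca = pca_scores(matrix, k=2)
    embedding_to_tsv(pca, matrix, cfg.RESULTS / "pca_coords.tsv")

    coords = mds.coordinates.to_numpy()
    pheno = matrix.samples["phenotype"].to_numpy()
    dm = squareform(pdist(coords))
    same = dm[np.equal.outer(pheno, pheno) & ~np.eye(len(pheno), dtype=bool)].mean()
    diff = dm[~np.equal.outer(pheno, pheno)].mean()
    print(
        f"MDS (distance = 1 - r): mean within-phenotype distance {same:.4f}, "
        f"between {diff:.4f} (ratio {same / diff:.2f}); "
        f"top-2 variance share {mds.proportion.sum():.1%}"
    )


if __name__ == "__main__":
    main()
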