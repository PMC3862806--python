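"""Sample-level structure: correlation distances, classical MDS, PCA scores.

Arrays are compared by the Pearson correlation of their gene-expression
vectors; the distance 1 - r feeds a classical (Torgerson) multidimensional
scaling so each array becomes a point in 2-D, the standard global QC view for
spotting phenotype clustering and outlier arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import AnalysisError
from .ingest import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances d = 1 - Pearson r, in [0, 2]."""

    distances: pd.DataFrame  # square, sample x sample

    @property
    def sample_ids(self) -> pd.Index:
        return self.distances.index

    def to_numpy(self) -> np.ndarray:
        return self.distances.to_numpy()


@dataclass
class Embedding:
    """Low-dimensional sample coordinates with spectrum bookkeeping."""

    coordinates: pd.DataFrame  # sample x k, columns dim1..dimk
    eigenvalues: np.ndarray  # full spectrum, non-increasing
    proportion: np.ndarray  # variance share of each kept dimension


def correlation_distance(matrix: ExpressionMatrix) -> DistanceMatrix:
    """All pairwise 1 - r distances between samples over retained genes."""
    if matrix.n_samples < 2 or matrix.n_genes < 3:
        raise AnalysisError("correlation_distance needs >=2 samples and >=3 genes")
    vals = matrix.values.to_numpy(dtype=float)
    sds = vals.std(axis=0)
    if (sds == 0).any():
        bad = matrix.sample_ids[int(np.argmax(sds == 0))]
        raise AnalysisError(f"zero-variance sample {bad!r}")
    corr = np.corrcoef(vals.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry
    return DistanceMatrix(
        pd.DataFrame(dist, index=matrix.sample_ids, columns=matrix.sample_ids)
    )


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    # reproducible orientation: largest-|loading| coordinate positive per axis
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def classical_mds(dist: DistanceMatrix, k: int = 2) -> Embedding:
    """Torgerson MDS: double-centred Gram eigendecomposition of the distances.

    Negative eigenvalues (non-Euclidean part of the distances) are truncated
    to zero with their total magnitude logged. Deterministic up to sign, which
    is fixed by the largest-loading convention.
    """
    D = dist.to_numpy()
    n = D.shape[0]
    if k >= n:
        raise AnalysisError(f"k={k} must be < number of samples ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg = eigval[eigval < 0]
    if len(neg):
        logger.info("classical_mds: truncated negative eigenvalue mass %.3g", -neg.sum())
    lam = np.clip(eigval[:k], 0.0, None)
    coords = _fix_signs(eigvec[:, :k] * np.sqrt(lam)[None, :])
    pos_total = eigval[eigval > 0].sum()
    proportion = lam / pos_total if pos_total > 0 else np.zeros(k)
    return Embedding(
        pd.DataFrame(
            coords,
            index=dist.sample_ids,
            columns=[f"dim{i + 1}" for i in range(k)],
        ),
        eigenvalues=eigval,
        proportion=proportion,
    )


def pca_scores(matrix: ExpressionMatrix, k: int = 2) -> Embedding:
    """Sample scores from PCA of the gene-centred expression matrix."""
    n = matrix.n_samples
    if k >= n:
        raise AnalysisError(f"k={k} must be < number of samples ({n})")
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=k, svd_solver="full")
    coords = _fix_signs(pca.fit_transform(X))
    return Embedding(
        pd.DataFrame(
            coords,
            index=matrix.sample_ids,
            columns=[f"dim{i + 1}" for i in range(k)],
        ),
        eigenvalues=pca.explained_variance_,
        proportion=pca.explained_variance_ratio_,
    )


def embedding_to_tsv(embedding: Embedding, matrix: ExpressionMatrix, path) -> None:
    """Coordinates TSV with group labels for colouring."""
    out = embedding.coordinates.copy()
    for col in matrix.samples.columns:
        out[col] = matrix.samples[col]
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
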