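"""Ordination of CLR-transformed communities.

A single PCA is fit jointly over all communities; the number of components
that exceed sequencing noise is estimated by a permutation test that
scrambles taxon identity within each sample and re-derives the eigenvalue
spectrum.  A metric MDS embedding of the Aitchison distance (Euclidean
distance between CLR vectors) is provided as an ordination cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

from .compositional import ClrMatrix, CountTable, clr_transform

__all__ = ["PcaModel", "fit_pca", "permutation_significance", "aitchison_mds"]


@dataclass
class PcaModel:
    """PCA of a CLR matrix with samples as observations and taxa as features.

    ``loadings`` rows are the orthonormal principal axes over taxa;
    ``scores`` are sample coordinates; ``feature_means`` are the per-taxon
    means subtracted before decomposition (needed to center new data the
    same way).  ``n_significant`` / ``permutation_spectra`` are filled in by
    :func:`permutation_significance`.
    """

    loadings: pd.DataFrame  # components x taxa
    scores: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    feature_means: pd.Series
    n_significant: int | None = None
    permutation_spectra: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def axis(self, index: int) -> pd.Series:
        """Loadings of principal component ``index`` (0-based) over taxa."""
        return self.loadings.iloc[index]

    def centered(self, clr: ClrMatrix) -> pd.DataFrame:
        """Center a CLR matrix (taxa x samples) by this model's feature means."""
        return clr.values.sub(self.feature_means, axis=0)


def fit_pca(clr: ClrMatrix) -> PcaModel:
    """Full PCA of a CLR matrix; eigenvalues sorted descending.

    Raises on degenerate input (fewer than 2 samples/taxa or zero total
    variance).
    """
    X = clr.values.to_numpy().T  # samples x taxa
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 taxa")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate input: no variance across samples")
    pca = PCA()
    scores = pca.fit_transform(X)
    comp_index = pd.Index([f"PC{i + 1}" for i in range(pca.n_components_)])
    return PcaModel(
        loadings=pd.DataFrame(pca.components_, index=comp_index, columns=clr.taxon_ids),
        scores=pd.DataFrame(scores, index=clr.sample_ids, columns=comp_index),
        eigenvalues=pca.explained_variance_,
        variance_fractions=pca.explained_variance_ratio_,
        feature_means=pd.Series(pca.mean_, index=clr.taxon_ids),
    )


def _eigen_spectrum(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Eigenvalues of the CLR+PCA of a raw count matrix (taxa x samples)."""
    logc = np.log(counts + pseudocount)
    clr = logc - logc.mean(axis=0, keepdims=True)
    X = clr.T
    Xc = X - X.mean(axis=0, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    return s**2 / (X.shape[0] - 1)


def permutation_significance(
    table: CountTable,
    n_perm: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Count leading PCA components that exceed within-sample permutation noise.

    Each permutation independently shuffles the taxon entries within every
    sample (destroying taxon identity while preserving each sample's count
    multiset), then re-applies pseudocount + CLR + PCA.  Component ``m`` is
    significant when the observed eigenvalue exceeds the ``1 - alpha``
    quantile of the permuted eigenvalue ``m``; counting proceeds from the
    first component and stops at the first failure.  The table should
    already be rare-filtered.

    Returns ``(n_significant, permutation_spectra)`` where the spectra array
    is ``n_perm x n_components``.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives a very coarse null quantile", stacklevel=2)
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy(dtype=float)
    observed = _eigen_spectrum(counts, pseudocount)
    spectra = np.empty((n_perm, observed.size))
    for b in range(n_perm):
        permuted = np.empty_like(counts)
        for j in range(counts.shape[1]):
            permuted[:, j] = rng.permutation(counts[:, j])
        spectra[b] = _eigen_spectrum(permuted, pseudocount)
    cutoffs = np.quantile(spectra, 1.0 - alpha, axis=0)
    n_significant = 0
    for m in range(observed.size):
        if observed[m] > cutoffs[m]:
            n_significant += 1
        else:
            break
    return n_significant, spectra


def aitchison_mds(
    table: CountTable,
    n_dims: int = 2,
    pseudocount: float = 1.0,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Aitchison distances (Euclidean on CLR) embedded by metric MDS (SMACOF).

    Returns ``(coordinates, stress, distance_matrix)``; coordinates are
    samples x n_dims.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for an MDS embedding")
    clr = clr_transform(table, pseudocount=pseudocount)
    dist = squareform(pdist(clr.values.to_numpy().T, metric="euclidean"))
    dist_df = pd.DataFrame(dist, index=table.sample_ids, columns=table.sample_ids)
    mds = MDS(
        n_components=n_dims,
        metric="precomputed",
        metric_mds=True,
        init="random",
        random_state=seed,
        normalized_stress=False,
        n_init=4,
    )
    coords = mds.fit_transform(dist)
    coords_df = pd.DataFrame(
        coords,
        index=table.sample_ids,
        columns=[f"MDS{i + 1}" for i in range(n_dims)],
    )
    return coords_df, float(mds.stress_), dist_df
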