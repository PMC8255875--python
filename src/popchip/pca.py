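"""Genotype-matrix principal component analysis for structure visualisation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class PCAResult:
    coordinates: np.ndarray       # samples x K scores
    variance_fractions: np.ndarray  # against the sum of all positive eigenvalues
    eigenvalues: np.ndarray
    sample_ids: list[str]
    breed_labels: list[str]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.coordinates[:, i] for i in range(self.k)}
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "breed": self.breed_labels, **cols}
        )

    def top_k_fraction(self, k: int | None = None) -> float:
        """Variance share of the first k PCs against the *retained* eigenvalue
        sum (the alternative denominator some tools report)."""
        k = k or self.k
        ev = self.eigenvalues[: len(self.variance_fractions)]
        return float(ev[:k].sum() / ev.sum())


def genotype_pca(ds: GenotypeDataset, k: int = 10) -> PCAResult:
    """PCA of the standardised dosage matrix.

    Missing dosages are mean-imputed per SNP; columns are centred by 2f and
    scaled by sqrt(2f(1-f)); SNPs with f in {0, 1} are dropped. Scores are
    eigenvectors of the sample-covariance (GRM) matrix scaled by
    sqrt(eigenvalue), with each component's largest-magnitude score made
    positive for determinism.
    """
    if ds.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    G = ds.calls.astype(float)
    G[G == MISSING] = np.nan
    f = np.nanmean(G, axis=0) / 2.0
    poly = np.isfinite(f) & (f > 0) & (f < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNP; PCA undefined")
    G = G[:, poly]
    f = f[poly]
    G = np.where(np.isnan(G), 2.0 * f, G)
    Z = (G - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))

    m = Z.shape[1]
    grm = Z @ Z.T / m
    eigval, eigvec = np.linalg.eigh(grm)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > 1e-12
    if not positive.any():
        raise ValueError("zero total variance; PCA undefined")
    total = eigval[positive].sum()

    k = min(k, int(positive.sum()))
    scores = eigvec[:, :k] * np.sqrt(eigval[:k])
    for comp in range(k):
        col = scores[:, comp]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, comp] = -col
    return PCAResult(
        coordinates=scores,
        variance_fractions=eigval[:k] / total,
        eigenvalues=eigval,
        sample_ids=list(ds.sample_ids),
        breed_labels=list(ds.breed_labels),
    )
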