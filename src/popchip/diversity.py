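"""Per-breed genetic-diversity statistics: MAF, Ho/He, informative SNPs and
IBS-based within-breed genetic distance."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class BreedDiversitySummary:
    breed_label: str
    n_samples: int
    mean_maf: float
    n_informative_snps: int
    mean_ho: float
    mean_he: float
    mean_d: float


def breed_allele_freqs(ds: GenotypeDataset, breed_label: str) -> pd.DataFrame:
    """Per-SNP allele_b frequency and MAF within one breed.

    SNPs with no non-missing call in the breed get NaN frequency; downstream
    means skip them (their count is visible as ``n_called == 0``).
    """
    idx = ds.breed_indices(breed_label)
    sub = ds.calls[idx]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    b_count = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, b_count / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(f, 1.0 - f)
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in ds.snps],
            "n_called": n_called,
            "freq_b": f,
            "maf": maf,
        }
    )


def heterozygosities(ds: GenotypeDataset, breed_label: str, corrected: bool = False):
    """Per-SNP observed (Ho) and expected (He = 2pq) heterozygosity and breed means.

    ``corrected=True`` applies the small-sample factor 2n/(2n-1) to He.
    Returns ``(per_snp_frame, mean_ho, mean_he)``.
    """
    idx = ds.breed_indices(breed_label)
    sub = ds.calls[idx]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    het = (sub == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    freqs = breed_allele_freqs(ds, breed_label)
    f = freqs["freq_b"].to_numpy()
    he = 2.0 * f * (1.0 - f)
    if corrected:
        with np.errstate(invalid="ignore", divide="ignore"):
            he = he * (2.0 * n_called) / np.maximum(2.0 * n_called - 1, 1)
    frame = pd.DataFrame(
        {"snp_id": freqs["snp_id"], "n_called": n_called, "ho": ho, "he": he}
    )
    # all-missing panel: means undefined rather than a numpy warning
    mean_ho = float(np.nanmean(ho)) if np.isfinite(ho).any() else float("nan")
    mean_he = float(np.nanmean(he)) if np.isfinite(he).any() else float("nan")
    return frame, mean_ho, mean_he


def informative_snp_count(
    ds: GenotypeDataset, breed_label: str, threshold: float = 0.05
) -> int:
    """Number of SNPs with within-breed MAF strictly above ``threshold``."""
    maf = breed_allele_freqs(ds, breed_label)["maf"].to_numpy()
    return int(np.sum(maf > threshold))


def ibs_distance(ds: GenotypeDataset, sample_i: str, sample_j: str) -> float:
    """Genotype IBS distance D = 1 - mean allele-sharing similarity.

    Per jointly called SNP the similarity is 1 (identical genotypes), 0.5
    (one shared allele) or 0 (opposite homozygotes); with 0/1/2 dosages this
    is ``1 - |g_i - g_j| / 2``.
    """
    gi = ds.calls[ds.sample_index(sample_i)]
    gj = ds.calls[ds.sample_index(sample_j)]
    both = (gi != MISSING) & (gj != MISSING)
    if not both.any():
        raise ValueError(
            f"no jointly called SNP between {sample_i!r} and {sample_j!r}"
        )
    diff = np.abs(gi[both].astype(np.int16) - gj[both].astype(np.int16))
    return float(diff.mean() / 2.0)


def breed_mean_distance(ds: GenotypeDataset, breed_label: str) -> float:
    """Unweighted mean pairwise IBS distance over the C(n,2) within-breed pairs."""
    idx = ds.breed_indices(breed_label)
    if idx.size < 2:
        raise ValueError(f"breed {breed_label!r} has fewer than 2 samples")
    dists = [
        ibs_distance(ds, ds.sample_ids[i], ds.sample_ids[j])
        for i, j in combinations(idx, 2)
    ]
    return float(np.mean(dists))


def breed_summary(ds: GenotypeDataset, breed_label: str) -> BreedDiversitySummary:
    freqs = breed_allele_freqs(ds, breed_label)
    _, mean_ho, mean_he = heterozygosities(ds, breed_label)
    return BreedDiversitySummary(
        breed_label=breed_label,
        n_samples=int(ds.breed_indices(breed_label).size),
        mean_maf=float(freqs["maf"].mean(skipna=True)),
        n_informative_snps=informative_snp_count(ds, breed_label),
        mean_ho=mean_ho,
        mean_he=mean_he,
        mean_d=breed_mean_distance(ds, breed_label),
    )


def diversity_table(ds: GenotypeDataset) -> pd.DataFrame:
    """One row per breed with the headline diversity columns (Ne is filled in
    by the LD module when the full pipeline runs)."""
    rows = []
    for breed in ds.breeds:
        s = breed_summary(ds, breed)
        rows.append(
            {
                "breed": s.breed_label,
                "n": s.n_samples,
                "maf": s.mean_maf,
                "informative_snps": s.n_informative_snps,
                "ho": s.mean_ho,
                "he": s.mean_he,
                "d": s.mean_d,
            }
        )
    return pd.DataFrame(rows)
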