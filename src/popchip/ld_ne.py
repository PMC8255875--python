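"""Pairwise genotypic r² to 5 Mb, distance binning, LD decay and LD-based Ne.

r² is the squared Pearson correlation between 0/1/2 dosage vectors over
jointly non-missing samples (composite LD — phase is not required). Effective
population size follows Ne = (1/4c) * (1/r² - 1) with c in Morgans; r² at
genetic distance c reflects Ne roughly T = 1/(2c) generations ago.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


def default_bin_edges_mb() -> list[float]:
    """0.01-Mb steps to 0.05 Mb, 0.05-Mb steps to 1 Mb, 1-Mb steps to 5 Mb."""
    edges = [0.0]
    edges += [round(0.01 * k, 6) for k in range(1, 5)]          # 0.01 .. 0.04
    edges += [round(0.05 * k, 6) for k in range(1, 21)]         # 0.05 .. 1.0
    edges += [float(k) for k in range(2, 6)]                    # 2 .. 5
    return edges


@dataclass
class LDProfile:
    breed_label: str
    bins: pd.DataFrame  # columns: lower_mb, upper_mb, mean_r2, n_pairs
    adjacent_mean_r2: float
    n_adjacent_pairs: int
    n_skipped_zero_variance: int = 0

    @property
    def r2_at_1mb(self) -> float:
        return self._bin_mean(1.0)

    @property
    def r2_at_5mb(self) -> float:
        return self._bin_mean(5.0)

    def _bin_mean(self, upper: float) -> float:
        row = self.bins[np.isclose(self.bins["upper_mb"], upper)]
        if row.empty or row["n_pairs"].iloc[0] == 0:
            return float("nan")
        return float(row["mean_r2"].iloc[0])


@dataclass
class NeEstimate:
    breed_label: str
    current_ne: float
    trajectory: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["t_generations", "ne"])
    )


# ---------------------------------------------------------------------------
# pairwise r2
# ---------------------------------------------------------------------------

def pairwise_r2(
    ds: GenotypeDataset,
    breed_label: str,
    max_dist_mb: float = 5.0,
    autosomes_only: bool = True,
) -> tuple[pd.DataFrame, int]:
    """All within-chromosome SNP pairs up to ``max_dist_mb`` apart for one breed.

    Returns ``(pairs, n_skipped)`` where ``pairs`` has columns
    ``chromosome, snp_i, snp_j, dist_bp, r2, adjacent`` and ``n_skipped``
    counts pairs dropped for zero variance or <2 joint calls.
    """
    idx = ds.breed_indices(breed_label)
    G = ds.calls[idx].astype(float)
    G[G == MISSING] = np.nan
    chroms = ds.chromosomes()
    pos = ds.positions()
    max_bp = max_dist_mb * 1e6

    frames = []
    n_skipped = 0
    for chrom in ds.chromosome_labels():
        if autosomes_only and not chrom.isdigit():
            continue
        mask = chroms == chrom
        p = pos[mask]
        X = G[:, mask]
        m = p.size
        if m < 2:
            continue
        order = np.argsort(p, kind="stable")
        p, X = p[order], X[:, order]
        for k in range(1, m):
            d = p[k:] - p[:-k]
            inside = d <= max_bp
            if not inside.any():
                break
            a = X[:, :-k][:, inside]
            b = X[:, k:][:, inside]
            r2, ok = _columnwise_r2(a, b)
            n_skipped += int((~ok).sum())
            ii = np.flatnonzero(inside)
            frames.append(
                pd.DataFrame(
                    {
                        "chromosome": chrom,
                        "snp_i": ii[ok],
                        "snp_j": ii[ok] + k,
                        "dist_bp": d[inside][ok],
                        "r2": r2[ok],
                        "adjacent": k == 1,
                    }
                )
            )
    if frames:
        pairs = pd.concat(frames, ignore_index=True)
    else:
        pairs = pd.DataFrame(
            columns=["chromosome", "snp_i", "snp_j", "dist_bp", "r2", "adjacent"]
        )
    return pairs, n_skipped


def _columnwise_r2(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r² between matched columns of ``a`` and ``b`` over joint non-NaN rows."""
    joint = ~np.isnan(a) & ~np.isnan(b)
    a = np.where(joint, a, 0.0)
    b = np.where(joint, b, 0.0)
    n = joint.sum(axis=0)
    sa, sb = a.sum(axis=0), b.sum(axis=0)
    saa, sbb, sab = (a * a).sum(axis=0), (b * b).sum(axis=0), (a * b).sum(axis=0)
    cov = n * sab - sa * sb
    var_a = n * saa - sa * sa
    var_b = n * sbb - sb * sb
    denom = var_a * var_b
    ok = (n >= 2) & (denom > 0)
    r2 = np.full(a.shape[1], np.nan)
    r2[ok] = (cov[ok] ** 2) / denom[ok]
    return r2, ok


# ---------------------------------------------------------------------------
# binning and decay
# ---------------------------------------------------------------------------

def bin_ld(
    pairs: pd.DataFrame,
    breed_label: str,
    edges_mb: list[float] | None = None,
    n_skipped: int = 0,
) -> LDProfile:
    """Assign pairs to distance bins (lower, upper] and average r² per bin.

    The "adjacent" summary uses physically adjacent SNP pairs regardless of
    their distance. Empty bins carry ``n_pairs = 0`` and NaN mean.
    """
    if edges_mb is None:
        edges_mb = default_bin_edges_mb()
    dist_mb = pairs["dist_bp"].to_numpy() / 1e6 if len(pairs) else np.array([])
    r2 = pairs["r2"].to_numpy() if len(pairs) else np.array([])
    rows = []
    for lo, hi in zip(edges_mb[:-1], edges_mb[1:]):
        sel = (dist_mb > lo) & (dist_mb <= hi)
        n = int(sel.sum())
        rows.append(
            {
                "lower_mb": lo,
                "upper_mb": hi,
                "mean_r2": float(r2[sel].mean()) if n else float("nan"),
                "n_pairs": n,
            }
        )
    if len(pairs):
        adj = pairs.loc[pairs["adjacent"], "r2"]
        adj_mean = float(adj.mean()) if len(adj) else float("nan")
        n_adj = int(len(adj))
    else:
        adj_mean, n_adj = float("nan"), 0
    return LDProfile(
        breed_label=breed_label,
        bins=pd.DataFrame(rows),
        adjacent_mean_r2=adj_mean,
        n_adjacent_pairs=n_adj,
        n_skipped_zero_variance=n_skipped,
    )


def ld_profile(
    ds: GenotypeDataset, breed_label: str, max_dist_mb: float = 5.0
) -> LDProfile:
    """Convenience wrapper: pairwise r² then the standard binning."""
    pairs, n_skipped = pairwise_r2(ds, breed_label, max_dist_mb)
    return bin_ld(pairs, breed_label, n_skipped=n_skipped)


def half_decay_distance(profile: LDProfile) -> float:
    """Smallest distance (Mb) where the linearly interpolated mean r² drops to
    half the adjacent-pair mean; NaN if never reached within the profile."""
    if not np.isfinite(profile.adjacent_mean_r2):
        return float("nan")
    target = profile.adjacent_mean_r2 / 2.0
    populated = profile.bins[profile.bins["n_pairs"] > 0]
    if populated.empty:
        return float("nan")
    x = populated["upper_mb"].to_numpy(dtype=float)
    y = populated["mean_r2"].to_numpy(dtype=float)
    x = np.concatenate([[0.0], x])
    y = np.concatenate([[profile.adjacent_mean_r2], y])
    for k in range(1, len(x)):
        if y[k] <= target:
            if y[k - 1] <= target:
                return float(x[k - 1])
            frac = (y[k - 1] - target) / (y[k - 1] - y[k])
            return float(x[k - 1] + frac * (x[k] - x[k - 1]))
    return float("nan")


# ---------------------------------------------------------------------------
# effective population size
# ---------------------------------------------------------------------------

def ne_from_r2(r2: float, c: float) -> float:
    """Ne = (1/4c) * (1/r² - 1) with c in Morgans."""
    if c <= 0:
        raise ValueError("genetic distance c must be positive")
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1] (r2 = 0 implies infinite Ne)")
    return (1.0 / (4.0 * c)) * (1.0 / r2 - 1.0)


def current_ne(
    profile: LDProfile,
    cm_per_mb: float = 1.0,
    sample_size: int | None = None,
    sample_correction: bool = False,
) -> float:
    """Current Ne from the mean r² of pairs ~1 Mb apart (the (0.95, 1] bin).

    ``sample_correction=True`` subtracts the finite-sample expectation 1/n
    from the mean r² before inversion (requires ``sample_size``).
    """
    r2 = profile.r2_at_1mb
    if not np.isfinite(r2):
        raise ValueError("no pairs in the 1 Mb bin")
    if sample_correction:
        if not sample_size:
            raise ValueError("sample_correction requires sample_size")
        r2 = r2 - 1.0 / sample_size
        if r2 <= 0:
            raise ValueError("corrected r2 is non-positive; Ne unidentifiable")
    c = 1.0 * cm_per_mb / 100.0
    return ne_from_r2(r2, c)


def past_ne_trajectory(
    profile: LDProfile,
    cm_per_mb: float = 1.0,
    sample_size: int | None = None,
    sample_correction: bool = False,
) -> pd.DataFrame:
    """Per-bin past Ne: at bin midpoint d Mb, c = d*cm_per_mb/100 Morgans,
    T = 1/(2c) generations ago, Ne(T) = (1/4c)(1/r² - 1). Sorted by T."""
    rows = []
    for _, row in profile.bins.iterrows():
        if row["n_pairs"] == 0 or not np.isfinite(row["mean_r2"]):
            continue
        d_mb = (row["lower_mb"] + row["upper_mb"]) / 2.0
        c = d_mb * cm_per_mb / 100.0
        r2 = row["mean_r2"]
        if sample_correction and sample_size:
            r2 = r2 - 1.0 / sample_size
        if not 0 < r2 <= 1:
            continue
        rows.append(
            {
                "t_generations": 1.0 / (2.0 * c),
                "distance_mb": d_mb,
                "ne": ne_from_r2(r2, c),
            }
        )
    out = pd.DataFrame(rows, columns=["t_generations", "distance_mb", "ne"])
    return out.sort_values("t_generations", ignore_index=True)


def ne_estimate(
    ds: GenotypeDataset,
    breed_label: str,
    cm_per_mb: float = 1.0,
    sample_correction: bool = False,
) -> NeEstimate:
    profile = ld_profile(ds, breed_label)
    n = int(ds.breed_indices(breed_label).size)
    return NeEstimate(
        breed_label=breed_label,
        current_ne=current_ne(profile, cm_per_mb, n, sample_correction),
        trajectory=past_ne_trajectory(profile, cm_per_mb, n, sample_correction),
    )
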