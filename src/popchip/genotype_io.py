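"""Reading, validating, filtering and writing SNP-array genotypes in PLINK text format.

Genotypes are stored as dosages of ``allele_b`` (0, 1, 2) with ``MISSING = -1``.
At load time ``allele_b`` is chosen as the minor allele (ties broken so that
``allele_b`` is the lexicographically greater base), which gives every dataset a
deterministic dosage orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: Chromosome labels treated as autosomes (all-digit labels).
AUTOSOMES = tuple(str(i) for i in range(1, 19))


class PlinkParseError(ValueError):
    """Malformed PED/MAP input (column counts, allele inconsistencies...)."""


class EmptyDatasetError(ValueError):
    """Raised when an operation would leave or receive no usable data."""


@dataclass(frozen=True)
class SNPRecord:
    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"negative position for SNP {self.snp_id}")


@dataclass(frozen=True)
class QCParams:
    """Per-SNP filters: call rate >= ``call_rate_min`` and pooled MAF >= ``maf_min``."""

    call_rate_min: float = 0.95
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")


def _chrom_sort_key(label: str) -> tuple[int, int, str]:
    if label.isdigit():
        return (0, int(label), "")
    return (1, 0, label)


@dataclass
class GenotypeDataset:
    """Samples x SNPs biallelic call matrix with breed labels and a physical map.

    ``calls[i, j]`` is the count of ``snps[j].allele_b`` carried by sample ``i``,
    or :data:`MISSING`.
    """

    sample_ids: list[str]
    breed_labels: list[str]
    snps: list[SNPRecord]
    calls: np.ndarray
    sex: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(self.breed_labels) != len(self.sample_ids):
            raise ValueError("breed label count does not match sample count")
        if any(not lab for lab in self.breed_labels):
            raise ValueError("breed labels must be non-empty")
        if not self.sex:
            self.sex = ["0"] * len(self.sample_ids)
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be 0/1/2 or MISSING")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def breeds(self) -> list[str]:
        """Distinct breed labels in first-seen order."""
        seen: dict[str, None] = {}
        for lab in self.breed_labels:
            seen.setdefault(lab)
        return list(seen)

    def breed_indices(self, breed_label: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.breed_labels) == breed_label)
        if idx.size == 0:
            raise KeyError(f"unknown breed label: {breed_label!r}")
        return idx

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def positions(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.snps], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps])

    def chromosome_labels(self) -> list[str]:
        """Distinct chromosome labels in genome order."""
        return sorted({s.chromosome for s in self.snps}, key=_chrom_sort_key)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            breed_labels=list(self.breed_labels),
            snps=[self.snps[j] for j in keep],
            calls=self.calls[:, keep].copy(),
            sex=list(self.sex),
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeDataset":
        keep = list(keep)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in keep],
            breed_labels=[self.breed_labels[i] for i in keep],
            snps=list(self.snps),
            calls=self.calls[keep, :].copy(),
            sex=[self.sex[i] for i in keep],
        )

    def sort_snps(self) -> "GenotypeDataset":
        order = sorted(
            range(self.n_snps),
            key=lambda j: (_chrom_sort_key(self.snps[j].chromosome), self.snps[j].position_bp),
        )
        return self.subset_snps(np.asarray(order))


def canonicalize_alleles(ds: GenotypeDataset) -> GenotypeDataset:
    """Re-orient dosages so allele_b is the minor allele (ties: greater base).

    The same rule :func:`read_plink` applies, so canonical datasets round-trip
    through PED/MAP exactly.
    """
    calls = ds.calls.copy()
    snps = list(ds.snps)
    for j, snp in enumerate(snps):
        col = calls[:, j]
        called = col != MISSING
        n_b = int(col[called].sum())
        n_a = 2 * int(called.sum()) - n_b
        flip = n_b > n_a or (n_b == n_a and snp.allele_b < snp.allele_a)
        if flip:
            calls[called, j] = 2 - col[called]
            snps[j] = dataclasses.replace(snp, allele_a=snp.allele_b, allele_b=snp.allele_a)
    return GenotypeDataset(
        sample_ids=list(ds.sample_ids),
        breed_labels=list(ds.breed_labels),
        snps=snps,
        calls=calls,
        sex=list(ds.sex),
    )


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------

def _read_map(map_path: Path) -> list[tuple[str, str, int]]:
    records = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PlinkParseError(
                    f"{map_path}:{lineno}: expected 4 columns "
                    f"(chrom, id, cM, bp), got {len(fields)}"
                )
            chrom, snp_id, _cm, bp = fields
            records.append((chrom, snp_id, int(bp)))
    if not records:
        raise PlinkParseError(f"{map_path}: empty MAP file")
    return records


def read_plink(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Load a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    The PED family-ID column is stored as the breed label; "0 0" genotypes
    become :data:`MISSING`; SNPs are sorted by (chromosome, position).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_records = _read_map(map_path)
    m = len(map_records)

    sample_ids: list[str] = []
    breed_labels: list[str] = []
    sexes: list[str] = []
    rows: list[np.ndarray] = []
    # first pass allele discovery per SNP, then recode
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns for "
                    f"{m} SNPs, got {len(fields)}"
                )
            fid, iid, _father, _mother, sex, _pheno = fields[:6]
            breed_labels.append(fid)
            sample_ids.append(iid)
            sexes.append(sex)
            allele_rows.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(m)]
            )
    if not sample_ids:
        raise PlinkParseError(f"{ped_path}: empty PED file")

    n = len(sample_ids)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    snps: list[SNPRecord] = []
    for j, (chrom, snp_id, bp) in enumerate(map_records):
        counts: dict[str, int] = {}
        for i in range(n):
            for al in allele_rows[i][j]:
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise PlinkParseError(
                f"SNP {snp_id}: more than 2 distinct alleles observed: "
                f"{sorted(counts)}"
            )
        if counts:
            # minor allele -> allele_b; ties: lexicographically greater base
            ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            allele_a = ordered[0][0]
            allele_b = ordered[1][0] if len(ordered) == 2 else "0"
        else:
            allele_a = allele_b = "0"
        snps.append(SNPRecord(snp_id, chrom, bp, allele_a, allele_b))
        for i in range(n):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue  # half-missing treated as missing
            calls[i, j] = (a1 == allele_b) + (a2 == allele_b)

    ds = GenotypeDataset(sample_ids, breed_labels, snps, calls, sexes)
    return ds.sort_snps()


def write_plink(ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP such that ``read_plink`` round-trips a canonical dataset."""
    if ds.n_samples == 0:
        raise EmptyDatasetError("cannot write a dataset with no samples")
    ped_path, map_path = Path(ped_path), Path(map_path)
    with open(map_path, "w") as fh:
        for snp in ds.snps:
            fh.write(f"{snp.chromosome}\t{snp.snp_id}\t0\t{snp.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.sample_ids):
            fields = [ds.breed_labels[i], sid, "0", "0", ds.sex[i], "-9"]
            row = ds.calls[i]
            for j, snp in enumerate(ds.snps):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [snp.allele_a, snp.allele_a]
                elif g == 1:
                    fields += [snp.allele_a, snp.allele_b]
                else:
                    fields += [snp.allele_b, snp.allele_b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def pooled_allele_counts(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (non-missing sample count, allele_b count) pooled over all breeds."""
    called = ds.calls != MISSING
    n_called = called.sum(axis=0)
    b_count = np.where(called, ds.calls, 0).sum(axis=0)
    return n_called, b_count


def apply_qc(
    ds: GenotypeDataset, qc: QCParams | None = None
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Filter SNPs by call rate and whole-dataset MAF.

    Returns the filtered dataset (sample set unchanged) and a removal log with
    columns ``snp_id`` and ``reason`` ("call_rate" or "maf").
    """
    if qc is None:
        qc = QCParams()
    if ds.n_samples == 0 or ds.n_snps == 0:
        raise EmptyDatasetError("dataset is empty")
    n_called, b_count = pooled_allele_counts(ds)
    call_rate = n_called / ds.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, b_count / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.where(np.isnan(f), 0.0, np.minimum(f, 1.0 - f))

    keep = np.ones(ds.n_snps, dtype=bool)
    removed: list[tuple[str, str]] = []
    for j in range(ds.n_snps):
        if call_rate[j] < qc.call_rate_min:
            keep[j] = False
            removed.append((ds.snps[j].snp_id, "call_rate"))
        elif maf[j] < qc.maf_min:
            keep[j] = False
            removed.append((ds.snps[j].snp_id, "maf"))
    if not keep.any():
        raise EmptyDatasetError("no SNPs remain after QC")
    log = pd.DataFrame(removed, columns=["snp_id", "reason"])
    return ds.subset_snps(keep), log


# ---------------------------------------------------------------------------
# Map summary
# ---------------------------------------------------------------------------

def summarize_map(ds: GenotypeDataset) -> tuple[pd.DataFrame, float]:
    """Per-chromosome SNP counts and adjacent spacing; grand mean across chromosomes.

    Spacing for a chromosome with fewer than 2 SNPs is NaN (undefined, not zero).
    The grand mean is the unweighted mean over chromosomes with defined spacing.
    """
    chroms = ds.chromosomes()
    pos = ds.positions()
    rows = []
    for chrom in ds.chromosome_labels():
        p = np.sort(pos[chroms == chrom])
        if p.size >= 2:
            spacing = float(np.diff(p).mean())
        else:
            spacing = float("nan")
        rows.append(
            {
                "chromosome": chrom,
                "n_snps": int(p.size),
                "mean_spacing_bp": spacing,
                "min_position_bp": int(p.min()) if p.size else np.nan,
                "max_position_bp": int(p.max()) if p.size else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    defined = table["mean_spacing_bp"].dropna()
    grand_mean = float(defined.mean()) if len(defined) else float("nan")
    return table, grand_mean
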