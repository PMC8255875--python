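"""Runs-of-homozygosity detection and the genomic inbreeding coefficient F_ROH.

A run is a maximal stretch of autosomal SNPs that starts and ends on a
homozygous call, contains at most ``max_het`` heterozygous and ``max_missing``
missing calls, has no internal adjacent-SNP gap above ``max_gap_kb``, and
passes the minimum homozygous-SNP-count / length / density thresholds.

The detector is a linear two-pointer scan emitting maximal qualifying
intervals left to right without overlap; tests cross-check it against a
brute-force enumeration of every contiguous interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class ROHParams:
    min_snps: int = 40                    # homozygous SNPs per run
    min_length_kb: float = 1000.0
    min_density_kb_per_snp: float = 1000.0  # at least one SNP per this many kb
    max_gap_kb: float = 1000.0
    max_het: int = 1
    max_missing: int = 5


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int      # SNPs spanned by the segment (incl. het/missing)
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_hom(self) -> int:
        return self.n_snps - self.n_het - self.n_missing


@dataclass(frozen=True)
class InbreedingSummary:
    sample_id: str
    n_segments: int
    total_length_bp: int
    f_roh: float


def autosome_length(ds: GenotypeDataset) -> int:
    """Length of the autosomal genome covered by SNPs: sum over autosomes of
    (max position - min position)."""
    chroms = ds.chromosomes()
    pos = ds.positions()
    total = 0
    found = False
    for chrom in ds.chromosome_labels():
        if not chrom.isdigit():
            continue
        p = pos[chroms == chrom]
        if p.size >= 2:
            total += int(p.max() - p.min())
            found = True
    if not found:
        raise ValueError("no autosomal SNPs with >= 2 positions")
    return total


def _segment_ok(
    pos: np.ndarray, calls: np.ndarray, i: int, j: int, params: ROHParams
) -> bool:
    """Does the closed SNP interval [i, j] qualify as a run? Used only for
    final threshold checks; the monotone constraints are enforced by the scan."""
    length = pos[j] - pos[i]
    n_total = j - i + 1
    n_het = int(np.sum(calls[i : j + 1] == 1))
    n_missing = int(np.sum(calls[i : j + 1] == MISSING))
    n_hom = n_total - n_het - n_missing
    if n_hom < params.min_snps:
        return False
    if length < params.min_length_kb * 1000.0:
        return False
    if length / n_total > params.min_density_kb_per_snp * 1000.0:
        return False
    return True


def _scan_chromosome(
    pos: np.ndarray, calls: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Maximal qualifying intervals on one chromosome, greedily left to right."""
    n = len(pos)
    is_hom = (calls == 0) | (calls == 2)
    is_het = calls == 1
    is_miss = calls == MISSING
    max_gap = params.max_gap_kb * 1000.0
    gap_ok = np.diff(pos) <= max_gap if n > 1 else np.array([], dtype=bool)

    het_cum = np.concatenate([[0], np.cumsum(is_het)])
    miss_cum = np.concatenate([[0], np.cumsum(is_miss)])

    out: list[tuple[int, int]] = []
    last_end = -1
    # two-pointer: for each candidate start, the furthest extension end is
    # non-decreasing, so e never moves backwards
    e = 0
    for s in range(n):
        if not is_hom[s] or s <= last_end:
            continue
        if e < s:
            e = s
        # extend e while adding SNP e+1 keeps all monotone constraints
        while e + 1 < n:
            if not gap_ok[e]:
                break
            n_het = het_cum[e + 2] - het_cum[s]
            n_miss = miss_cum[e + 2] - miss_cum[s]
            if n_het > params.max_het or n_miss > params.max_missing:
                break
            e += 1
        # trim to the last homozygous call
        j = e
        while j >= s and not is_hom[j]:
            j -= 1
        if j > s and _segment_ok(pos, calls, s, j, params):
            # keep only if maximal: a previous start would have had e >= this;
            # by construction the first qualifying s after last_end is maximal
            out.append((s, j))
            last_end = j
        # a start strictly inside a failed candidate cannot extend further
        # unless it drops a het/missing; the loop naturally retries each hom s
    return out


def detect_roh(
    ds: GenotypeDataset, sample_id: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Detect runs of homozygosity on the autosomes of one individual."""
    if params is None:
        params = ROHParams()
    si = ds.sample_index(sample_id)
    chroms = ds.chromosomes()
    pos = ds.positions()
    segments: list[ROHSegment] = []
    for chrom in ds.chromosome_labels():
        if not chrom.isdigit():
            continue  # autosomes only
        mask = chroms == chrom
        p = pos[mask]
        c = ds.calls[si, mask]
        order = np.argsort(p, kind="stable")
        p, c = p[order], c[order]
        for s, j in _scan_chromosome(p, c, params):
            seg_calls = c[s : j + 1]
            segments.append(
                ROHSegment(
                    sample_id=sample_id,
                    chromosome=chrom,
                    start_bp=int(p[s]),
                    end_bp=int(p[j]),
                    n_snps=int(j - s + 1),
                    n_het=int(np.sum(seg_calls == 1)),
                    n_missing=int(np.sum(seg_calls == MISSING)),
                )
            )
    return segments


def froh(
    ds: GenotypeDataset, sample_id: str, segments: list[ROHSegment]
) -> InbreedingSummary:
    """F_ROH = total ROH length / SNP-covered autosome length."""
    l_auto = autosome_length(ds)
    by_chrom: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp < a.end_bp:
                raise ValueError(
                    f"overlapping ROH segments on chromosome {a.chromosome}"
                )
    total = sum(seg.length_bp for seg in segments)
    return InbreedingSummary(
        sample_id=sample_id,
        n_segments=len(segments),
        total_length_bp=int(total),
        f_roh=total / l_auto,
    )


def breed_roh_table(
    ds: GenotypeDataset, params: ROHParams | None = None
) -> pd.DataFrame:
    """Per-breed mean/SD/min/max of segment count, total length and F_ROH.

    SD is the sample standard deviation (ddof=1); single-sample breeds report
    SD 0 with ``sd_defined = False``.
    """
    rows = []
    for breed in ds.breeds:
        summaries = []
        for i in ds.breed_indices(breed):
            sid = ds.sample_ids[i]
            summaries.append(froh(ds, sid, detect_roh(ds, sid, params)))
        n_seg = np.array([s.n_segments for s in summaries], dtype=float)
        tot_kb = np.array([s.total_length_bp / 1000.0 for s in summaries])
        fr = np.array([s.f_roh for s in summaries])
        multi = len(summaries) > 1
        rows.append(
            {
                "breed": breed,
                "n": len(summaries),
                "n_seg_mean": n_seg.mean(),
                "n_seg_sd": n_seg.std(ddof=1) if multi else 0.0,
                "n_seg_min": n_seg.min(),
                "n_seg_max": n_seg.max(),
                "total_kb_mean": tot_kb.mean(),
                "total_kb_sd": tot_kb.std(ddof=1) if multi else 0.0,
                "total_kb_min": tot_kb.min(),
                "total_kb_max": tot_kb.max(),
                "froh_mean": fr.mean(),
                "froh_sd": fr.std(ddof=1) if multi else 0.0,
                "sd_defined": multi,
            }
        )
    return pd.DataFrame(rows)
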