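"""Forward-time Wright-Fisher multi-breed simulator with known truth values.

Populations are diploid and randomly mating with discrete generations, Poisson
recombination, no mutation (standing variation only, as on a SNP chip) and an
arbitrary breed-split topology. Emits :class:`~popchip.genotype_io.GenotypeDataset`
objects (writable to PED/MAP) together with the quantities the generator knows
exactly: per-branch sizes, expected drift F_ST, and pedigree inbreeding for the
sib-mating program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeDataset,
    SNPRecord,
    canonicalize_alleles,
)

_BASES = np.array(list("ACGT"))


@dataclass
class BranchSpec:
    """One branch of the breed-split tree: a population of diploid size
    ``size`` evolving for ``generations`` generations, then splitting into
    ``children`` (leaves are named breeds)."""

    name: str
    size: int
    generations: int
    children: list["BranchSpec"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"branch {self.name}: size must be positive")
        if self.generations < 0:
            raise ValueError(f"branch {self.name}: negative duration")

    def leaves(self) -> list["BranchSpec"]:
        if not self.children:
            return [self]
        out: list[BranchSpec] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class AdmixtureEvent:
    """At ``generation`` of the target branch, each parent draw comes from the
    source breed's gene pool with probability ``proportion``."""

    source: str
    target: str
    proportion: float
    generation: int

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion < 1.0:
            raise ValueError("admixture proportion must be in (0, 1)")


@dataclass
class SimulationConfig:
    tree: BranchSpec
    n_chromosomes: int = 2
    chrom_length_mb: float = 100.0
    n_snps_per_chrom: int = 1000
    cm_per_mb: float = 1.0
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    samples_per_breed: int = 25
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    missing_rate: float = 0.01
    position_jitter_bp: int = 0
    canonical_alleles: bool = True
    #: draw sampled individuals with replacement (i.i.d. sampling, as the
    #: variance-component F_ST estimator assumes); default is a census-style
    #: draw without replacement
    sample_with_replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.n_snps_per_chrom <= 0:
            raise ValueError("need at least one chromosome and one SNP")
        lo, hi = self.founder_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for leaf in self.tree.leaves():
            if self.samples_per_breed > 2 * leaf.size:
                raise ValueError(
                    f"samples_per_breed={self.samples_per_breed} exceeds 2N of "
                    f"breed {leaf.name}"
                )


@dataclass
class SimulationTruth:
    """Generator-side ground truth for a completed run."""

    founder_freqs: np.ndarray  # allele_b frequency in the founder pool
    expected_fst_vs_founder: dict[str, float]  # 1 - prod(1 - 1/2N)^t along path
    branch_sizes: dict[str, int]
    pedigree_f: dict[str, float] = field(default_factory=dict)  # sample_id -> F


# ---------------------------------------------------------------------------
# core machinery
# ---------------------------------------------------------------------------

def _snp_layout(config: SimulationConfig, rng: np.random.Generator):
    """Evenly spaced positions (optional jitter) and chromosome boundaries."""
    m = config.n_snps_per_chrom
    spacing = config.chrom_length_mb * 1e6 / m
    chrom_labels: list[str] = []
    positions: list[int] = []
    for c in range(config.n_chromosomes):
        base = (np.arange(m) + 1) * spacing
        if config.position_jitter_bp:
            base = base + rng.integers(
                -config.position_jitter_bp, config.position_jitter_bp + 1, size=m
            )
        base = np.maximum(1, np.round(base)).astype(np.int64)
        base = np.sort(base)
        chrom_labels += [str(c + 1)] * m
        positions += base.tolist()
    return np.array(chrom_labels), np.array(positions, dtype=np.int64)


def _gamete(
    hap_pair: np.ndarray,
    chrom_slices: list[slice],
    chrom_pos: list[np.ndarray],
    morgans_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine one parent's two haplotypes into a single gamete."""
    out = np.empty(hap_pair.shape[1], dtype=np.int8)
    for sl, pos in zip(chrom_slices, chrom_pos):
        span = float(pos[-1] - pos[0]) if pos.size > 1 else 0.0
        n_x = rng.poisson(span * morgans_per_bp) if span > 0 else 0
        start = rng.integers(0, 2)
        if n_x == 0:
            out[sl] = hap_pair[start, sl]
            continue
        cuts = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
        parity = (start + np.searchsorted(cuts, pos, side="right")) % 2
        seg = hap_pair[:, sl]
        out[sl] = np.where(parity == 0, seg[0], seg[1])
    return out


class _Pool:
    """A population's haplotypes: shape (2N, n_snps), row pairs are individuals."""

    def __init__(self, haps: np.ndarray):
        self.haps = haps

    @property
    def n_ind(self) -> int:
        return self.haps.shape[0] // 2

    def next_generation(
        self,
        n_next: int,
        layout,
        rng: np.random.Generator,
        migrant_pool: "_Pool | None" = None,
        migrant_prob: float = 0.0,
    ) -> "_Pool":
        chrom_slices, chrom_pos, morgans_per_bp = layout
        out = np.empty((2 * n_next, self.haps.shape[1]), dtype=np.int8)
        for k in range(n_next):
            for g in range(2):
                pool = self
                if migrant_pool is not None and rng.random() < migrant_prob:
                    pool = migrant_pool
                p = int(rng.integers(0, pool.n_ind))
                out[2 * k + g] = _gamete(
                    pool.haps[2 * p : 2 * p + 2],
                    chrom_slices,
                    chrom_pos,
                    morgans_per_bp,
                    rng,
                )
        return _Pool(out)

    def offspring_of_pair(
        self, n_next: int, layout, rng: np.random.Generator
    ) -> "_Pool":
        """Offspring of individuals 0 and 1 (one gamete from each parent)."""
        chrom_slices, chrom_pos, morgans_per_bp = layout
        out = np.empty((2 * n_next, self.haps.shape[1]), dtype=np.int8)
        for k in range(n_next):
            for g in range(2):
                out[2 * k + g] = _gamete(
                    self.haps[2 * g : 2 * g + 2],
                    chrom_slices,
                    chrom_pos,
                    morgans_per_bp,
                    rng,
                )
        return _Pool(out)


def _make_layout(config: SimulationConfig, chrom_labels, positions):
    chrom_slices, chrom_pos = [], []
    start = 0
    for c in range(config.n_chromosomes):
        stop = start + config.n_snps_per_chrom
        chrom_slices.append(slice(start, stop))
        chrom_pos.append(positions[start:stop])
        start = stop
    morgans_per_bp = config.cm_per_mb / 100.0 / 1e6
    return chrom_slices, chrom_pos, morgans_per_bp


def _build_dataset(
    config: SimulationConfig,
    chrom_labels: np.ndarray,
    positions: np.ndarray,
    genotype_blocks: list[tuple[str, np.ndarray]],
    rng: np.random.Generator,
) -> GenotypeDataset:
    m = len(chrom_labels)
    allele_idx = np.empty((m, 2), dtype=np.int64)
    for j in range(m):
        allele_idx[j] = rng.choice(4, size=2, replace=False)
    sample_ids, breed_labels, rows = [], [], []
    for breed, g in genotype_blocks:
        for i in range(g.shape[0]):
            sample_ids.append(f"{breed}_{i + 1}")
            breed_labels.append(breed)
            rows.append(g[i])
    calls = np.vstack(rows).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING
    snps = [
        SNPRecord(
            snp_id=f"snp_{chrom_labels[j]}_{j + 1}",
            chromosome=str(chrom_labels[j]),
            position_bp=int(positions[j]),
            allele_a=str(_BASES[allele_idx[j, 0]]),
            allele_b=str(_BASES[allele_idx[j, 1]]),
        )
        for j in range(m)
    ]
    ds = GenotypeDataset(sample_ids, breed_labels, snps, calls)
    if config.canonical_alleles:
        ds = canonicalize_alleles(ds)
    return ds


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def simulate_breeds(config: SimulationConfig) -> tuple[GenotypeDataset, SimulationTruth]:
    """Run the breed-split tree forward in time and sample the leaf breeds.

    Founder haplotypes are drawn in linkage equilibrium with per-SNP allele_b
    frequency uniform on ``founder_maf_range``. Expected drift differentiation
    versus the founder pool accumulates as ``1 - prod(1 - 1/(2N_b))^t_b`` along
    each leaf's path.
    """
    rng = np.random.default_rng(config.seed)
    chrom_labels, positions = _snp_layout(config, rng)
    m = len(chrom_labels)
    layout = _make_layout(config, chrom_labels, positions)

    lo, hi = config.founder_maf_range
    founder_freqs = rng.uniform(lo, hi, size=m)

    root_pool = _Pool(
        (rng.random((2 * config.tree.size, m)) < founder_freqs).astype(np.int8)
    )

    leaf_pools: dict[str, _Pool] = {}
    drift_factor: dict[str, float] = {}
    branch_sizes: dict[str, int] = {}
    admix_by_target: dict[str, list[AdmixtureEvent]] = {}
    for ev in config.admixture_events:
        admix_by_target.setdefault(ev.target, []).append(ev)

    def evolve(branch: BranchSpec, pool: _Pool, survival: float) -> None:
        branch_sizes[branch.name] = branch.size
        events = admix_by_target.get(branch.name, [])
        for gen in range(branch.generations):
            migrant_pool, migrant_prob = None, 0.0
            for ev in events:
                if ev.generation == gen:
                    src = leaf_pools.get(ev.source)
                    if src is None:
                        raise ValueError(
                            f"admixture source {ev.source!r} not yet simulated "
                            f"(sources must be earlier-listed leaves)"
                        )
                    migrant_pool, migrant_prob = src, ev.proportion
            pool = pool.next_generation(
                branch.size, layout, rng, migrant_pool, migrant_prob
            )
            survival *= 1.0 - 1.0 / (2 * branch.size)
        if not branch.children:
            leaf_pools[branch.name] = pool
            drift_factor[branch.name] = survival
        else:
            for child in branch.children:
                evolve(child, _Pool(pool.haps.copy()), survival)

    evolve(config.tree, root_pool, 1.0)

    blocks = []
    for leaf in config.tree.leaves():
        pool = leaf_pools[leaf.name]
        pick = rng.choice(
            pool.n_ind,
            size=config.samples_per_breed,
            replace=config.sample_with_replacement,
        )
        g = pool.haps[2 * pick] + pool.haps[2 * pick + 1]
        blocks.append((leaf.name, g))

    ds = _build_dataset(config, chrom_labels, positions, blocks, rng)
    truth = SimulationTruth(
        founder_freqs=founder_freqs,
        expected_fst_vs_founder={
            name: 1.0 - f for name, f in drift_factor.items()
        },
        branch_sizes=branch_sizes,
    )
    return ds, truth


def pedigree_f_sib_line(t: int) -> float:
    """Pedigree inbreeding after ``t`` rounds of full-sib mating:
    F_t = 0.25 * (1 + 2 F_{t-1} + F_{t-2}), F_0 = F_{-1} = 0."""
    if t < 0:
        raise ValueError("t must be >= 0")
    f_prev2, f_prev1 = 0.0, 0.0
    for _ in range(t):
        f_prev2, f_prev1 = f_prev1, 0.25 * (1 + 2 * f_prev1 + f_prev2)
    return f_prev1


def simulate_inbred_line(
    config: SimulationConfig,
    sib_generations: int,
    n_offspring: int = 4,
    breed_label: str = "inbred",
) -> tuple[GenotypeDataset, dict[str, float]]:
    """Full-sib mating line: two unrelated founders, ``sib_generations`` rounds
    of brother-sister mating, then ``n_offspring`` offspring of the final pair.

    Returns the offspring dataset and their (identical) pedigree F values.
    """
    if sib_generations < 1:
        raise ValueError("sib_generations must be >= 1")
    rng = np.random.default_rng(config.seed)
    chrom_labels, positions = _snp_layout(config, rng)
    m = len(chrom_labels)
    layout = _make_layout(config, chrom_labels, positions)
    lo, hi = config.founder_maf_range
    founder_freqs = rng.uniform(lo, hi, size=m)

    # founders: one unrelated pair; each round mates the current (sib) pair
    pair = _Pool((rng.random((4, m)) < founder_freqs).astype(np.int8))
    for _ in range(sib_generations):
        pair = pair.offspring_of_pair(2, layout, rng)
    final = pair.offspring_of_pair(n_offspring, layout, rng)
    # the sampled individuals are offspring of the last sib pair, one more
    # mating round, so they carry F_{sib_generations}
    g = final.haps[0::2] + final.haps[1::2]
    ds = _build_dataset(config, chrom_labels, positions, [(breed_label, g)], rng)
    f_val = pedigree_f_sib_line(sib_generations)
    ped_f = {sid: f_val for sid in ds.sample_ids}
    return ds, ped_f
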