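"""Between-breed differentiation: Weir-Cockerham F_ST variance components,
Tajima-Nei distances on breed consensus sequences, and neighbour-joining.

The F_ST estimator is the two-level (population / individual) variance
decomposition for diploids; the headline value is the ratio-of-sums
Σa / Σ(a+b+c) over SNPs, the per-SNP-mean variant is reported alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import breed_allele_freqs
from .genotype_io import MISSING, GenotypeDataset

_IUPAC = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}

_NUCS = "ACGT"


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    breed_pair: tuple[str, str]
    a: np.ndarray  # among-population component, per SNP
    b: np.ndarray  # among-individual-within component
    c: np.ndarray  # within-individual component
    genomewide_weighted: float  # sum(a) / sum(a+b+c)
    genomewide_mean: float      # mean of per-SNP ratios

    @property
    def clamped_weighted(self) -> float:
        """Weighted estimate clamped at 0 for reporting."""
        return max(0.0, self.genomewide_weighted)


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP variance components for r populations (rows of n/p/h are pops).

    n: called sample sizes, p: allele frequencies, h: observed heterozygote
    proportions; all shape (r, n_snps).
    """
    r = n.shape[0]
    n_bar = n.mean(axis=0)
    n_sum = n.sum(axis=0)
    nc = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1)
    p_bar = (n * p).sum(axis=0) / n_sum
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=0) / n_sum

    a = (n_bar / nc) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def wc_fst(ds: GenotypeDataset, breed_a: str, breed_b: str) -> FstResult:
    """Weir-Cockerham F_ST between two breeds over all usable SNPs.

    SNPs where either breed has no called sample, or where both breeds are
    jointly monomorphic (zero denominator), are excluded from the sums.
    """
    stats = []
    for breed in (breed_a, breed_b):
        idx = ds.breed_indices(breed)
        if idx.size < 2:
            raise ValueError(f"breed {breed!r} needs >= 2 samples for F_ST")
        sub = ds.calls[idx]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        p = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, (sub == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        stats.append((n, p, h))

    n = np.vstack([s[0] for s in stats])
    p = np.vstack([s[1] for s in stats])
    h = np.vstack([s[2] for s in stats])
    usable = (n >= 1).all(axis=0) & (n.mean(axis=0) > 1)
    n, p, h = n[:, usable], p[:, usable], h[:, usable]
    if n.shape[1] == 0:
        raise ValueError("no SNP with calls in both breeds")

    a, b, c = _wc_components(n, p, h)
    denom = a + b + c
    total = float(denom.sum())
    if total <= 0:
        raise ValueError(
            f"F_ST undefined for ({breed_a}, {breed_b}): "
            "no polymorphism in the joint sample"
        )
    pos = denom > 0
    per_snp = a[pos] / denom[pos]
    return FstResult(
        breed_pair=(breed_a, breed_b),
        a=a,
        b=b,
        c=c,
        genomewide_weighted=float(a.sum() / total),
        genomewide_mean=float(per_snp.mean()),
    )


# ---------------------------------------------------------------------------
# consensus sequences and Tajima-Nei distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusSequence:
    breed_label: str
    symbols: str  # one char per SNP: base, IUPAC ambiguity, or '-'


def consensus_sequence(ds: GenotypeDataset, breed_label: str) -> ConsensusSequence:
    """Majority allele per SNP; exact 50/50 ties become the two-base IUPAC
    ambiguity code; SNPs with no call in the breed become '-'."""
    freqs = breed_allele_freqs(ds, breed_label)
    f = freqs["freq_b"].to_numpy()
    n_called = freqs["n_called"].to_numpy()
    out = []
    for j, snp in enumerate(ds.snps):
        if n_called[j] == 0:
            out.append("-")
        elif snp.allele_b == "0" or f[j] < 0.5:
            out.append(snp.allele_a)
        elif f[j] > 0.5:
            out.append(snp.allele_b)
        else:
            pair = frozenset((snp.allele_a, snp.allele_b))
            out.append(_IUPAC.get(pair, "-"))
    return ConsensusSequence(breed_label, "".join(out))


def tajima_nei_distance(seq_x: str, seq_y: str) -> float:
    """Equal-input (Tajima-Nei 1984) distance with pairwise deletion.

    Sites with a gap or non-ACGT symbol in either sequence are removed.
    With q_i the base frequencies pooled over the two retained sequences,
    x_ij the fraction of retained sites showing the unordered differing pair
    {i, j}, and p = Σ x_ij:

        h = Σ_{i<j} x_ij² / (2 q_i q_j)
        b = (1 - Σ q_i² + p²/h) / 2
        d = -b ln(1 - p/b)

    Reduces to the Jukes-Cantor form when base frequencies are equal.
    """
    if len(seq_x) != len(seq_y):
        raise ValueError("sequences differ in length")
    xs, ys = [], []
    for cx, cy in zip(seq_x.upper(), seq_y.upper()):
        if cx in _NUCS and cy in _NUCS:
            xs.append(cx)
            ys.append(cy)
    n_sites = len(xs)
    if n_sites == 0:
        raise ValueError("no jointly unambiguous sites after pairwise deletion")

    diffs = [(cx, cy) for cx, cy in zip(xs, ys) if cx != cy]
    p = len(diffs) / n_sites
    if p == 0.0:
        return 0.0

    counts = {nuc: 0 for nuc in _NUCS}
    for c in itertools.chain(xs, ys):
        counts[c] += 1
    q = {nuc: counts[nuc] / (2 * n_sites) for nuc in _NUCS}

    pair_counts: dict[frozenset, int] = {}
    for cx, cy in diffs:
        key = frozenset((cx, cy))
        pair_counts[key] = pair_counts.get(key, 0) + 1

    h = 0.0
    for key, cnt in pair_counts.items():
        i, j = sorted(key)
        x_ij = cnt / n_sites
        h += x_ij**2 / (2.0 * q[i] * q[j])

    b = 0.5 * (1.0 - sum(v**2 for v in q.values()) + p**2 / h)
    if p >= b:
        raise ValueError(f"distance saturated: p={p:.4f} >= b={b:.4f}")
    return -b * math.log(1.0 - p / b)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def distance_matrix(ds: GenotypeDataset) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Breed x breed (Tajima-Nei on consensus sequences, weighted W&C F_ST)."""
    breeds = ds.breeds
    if len(breeds) < 2:
        raise ValueError("need >= 2 breeds")
    k = len(breeds)
    tn = np.zeros((k, k))
    fst = np.zeros((k, k))
    seqs = {b: consensus_sequence(ds, b).symbols for b in breeds}
    for i, j in itertools.combinations(range(k), 2):
        try:
            d = tajima_nei_distance(seqs[breeds[i]], seqs[breeds[j]])
        except ValueError as exc:
            raise ValueError(
                f"Tajima-Nei failed for pair ({breeds[i]}, {breeds[j]}): {exc}"
            ) from exc
        tn[i, j] = tn[j, i] = d
        res = wc_fst(ds, breeds[i], breeds[j])
        fst[i, j] = fst[j, i] = res.genomewide_weighted
    return DistanceMatrix(breeds, tn), DistanceMatrix(breeds, fst)


def fst_tn_table(tn: DistanceMatrix, fst: DistanceMatrix) -> pd.DataFrame:
    """Square table with F_ST below the diagonal and the evolutionary distance
    above it (diagonal blank)."""
    labels = fst.labels
    out = pd.DataFrame("", index=labels, columns=labels, dtype=object)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i > j:
                out.iloc[i, j] = f"{fst.values[i, j]:.4f}"
            elif i < j:
                out.iloc[i, j] = f"{tn.values[i, j]:.4f}"
            else:
                out.iloc[i, j] = "-"
    return out


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(
            f"{child._nwk()}:{length:.6g}" for child, length in self.children
        )
        return f"({inner})" + (self.label or "")

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label else []
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out


@dataclass
class PhyloTree:
    root: TreeNode
    n_clamped_branches: int = 0

    def newick(self) -> str:
        return self.root.newick()


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Classic neighbour-joining (Q-matrix agglomeration) with deterministic
    lexicographic tie-breaking and non-negative branch lengths.

    Negative branch lengths are clamped to 0 with the deficit moved onto the
    sister branch, so pairwise path lengths through the join are preserved.
    """
    k = len(dm.labels)
    if k < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if not np.allclose(np.diag(dm.values), 0.0):
        raise ValueError("distance matrix diagonal must be zero")

    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    names: list[str] = list(dm.labels)  # for deterministic tie-breaks
    d = dm.values.astype(float).copy()
    active = list(range(k))
    n_clamped = 0

    def clamp(v1: float, v2: float) -> tuple[float, float, int]:
        c = 0
        if v1 < 0:
            v2 += v1
            v1 = 0.0
            c += 1
        if v2 < 0:
            v1 += v2
            v2 = 0.0
            c += 1
        return max(v1, 0.0), max(v2, 0.0), c

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - row_sums[i] - row_sums[j]
                key = tuple(sorted((names[active[i]], names[active[j]])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[3]
                ):
                    best = (q, i, j, key)
        _, bi, bj, _ = best
        gi, gj = active[bi], active[bj]
        dij = d[gi, gj]
        vi = 0.5 * dij + (row_sums[bi] - row_sums[bj]) / (2 * (m - 2))
        vj = dij - vi
        vi, vj, c = clamp(vi, vj)
        n_clamped += c

        new = TreeNode(children=[(nodes[gi], vi), (nodes[gj], vj)])
        nodes.append(new)
        names.append(min(names[gi], names[gj]))
        gnew = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for ga in active:
            if ga in (gi, gj):
                continue
            d[gnew, ga] = d[ga, gnew] = 0.5 * (d[gi, ga] + d[gj, ga] - dij)
        active = [g for g in active if g not in (gi, gj)] + [gnew]

    # resolve the final three nodes around one internal vertex
    ga, gb, gc = active
    va = 0.5 * (d[ga, gb] + d[ga, gc] - d[gb, gc])
    vb = 0.5 * (d[ga, gb] + d[gb, gc] - d[ga, gc])
    vc = 0.5 * (d[ga, gc] + d[gb, gc] - d[ga, gb])
    lens = [va, vb, vc]
    for idx in range(3):
        if lens[idx] < 0:
            n_clamped += 1
            lens[idx] = 0.0
    root = TreeNode(
        children=[
            (nodes[ga], lens[0]),
            (nodes[gb], lens[1]),
            (nodes[gc], lens[2]),
        ]
    )
    return PhyloTree(root=root, n_clamped_branches=n_clamped)
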