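import itertools
import math

import dendropy
import numpy as np
import pytest

from popchip.differentiation import (
    DistanceMatrix,
    consensus_sequence,
    distance_matrix,
    fst_tn_table,
    nj_tree,
    tajima_nei_distance,
    wc_fst,
)
from popchip.genotype_io import MISSING
from popchip.simulate import BranchSpec, SimulationConfig, simulate_breeds

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent scalar implementation of the two-level variance components,
# written straight from the published per-locus formulas
# ---------------------------------------------------------------------------

def oracle_wc_single_locus(genos_by_pop):
    """Weighted components for one locus; genos_by_pop: list of 0/1/2 lists."""
    r = len(genos_by_pop)
    n = [len(g) for g in genos_by_pop]
    p = [sum(g) / (2 * len(g)) for g in genos_by_pop]
    h = [sum(1 for x in g if x == 1) / len(g) for g in genos_by_pop]
    n_sum = sum(n)
    n_bar = n_sum / r
    nc = (n_sum - sum(x * x for x in n) / n_sum) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / n_sum
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / n_sum
    a = (n_bar / nc) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def oracle_weighted_fst(calls_a, calls_b):
    """Ratio-of-sums over loci, skipping loci without calls in both pops."""
    sum_a = sum_abc = 0.0
    for j in range(calls_a.shape[1]):
        ga = [int(x) for x in calls_a[:, j] if x != MISSING]
        gb = [int(x) for x in calls_b[:, j] if x != MISSING]
        if not ga or not gb or (len(ga) + len(gb)) / 2 <= 1:
            continue
        a, b, c = oracle_wc_single_locus([ga, gb])
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


class TestWCFst:
    def test_textbook_toy(self):
        # pop1: 6 AA, 4 Aa; pop2: 2 AA, 3 Aa, 5 aa  (counting the 'a' allele)
        p1 = [0] * 6 + [1] * 4
        p2 = [0] * 2 + [1] * 3 + [2] * 5
        calls = np.array([p1 + p2], dtype=np.int8).T
        ds = make_dataset(calls, breeds=["P1"] * 10 + ["P2"] * 10)
        res = wc_fst(ds, "P1", "P2")
        # frozen from the independent scalar computation above
        assert res.genomewide_weighted == pytest.approx(0.3032015065913372, abs=1e-12)
        a, b, c = oracle_wc_single_locus([p1, p2])
        assert res.a[0] == pytest.approx(a, abs=1e-12)
        assert res.b[0] == pytest.approx(b, abs=1e-12)
        assert res.c[0] == pytest.approx(c, abs=1e-12)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.1, 0.5, size=400)
        calls = rng.binomial(2, freqs, size=(100, 400)).astype(np.int8)
        ds = make_dataset(
            calls,
            positions=[1000 * (j + 1) for j in range(400)],
            breeds=["P1"] * 50 + ["P2"] * 50,
        )
        res = wc_fst(ds, "P1", "P2")
        assert abs(res.genomewide_weighted) < 0.01

    def test_fixed_difference_near_one(self):
        calls = np.array([[0] * 100 + [2] * 100], dtype=np.int8).T
        ds = make_dataset(calls, breeds=["P1"] * 100 + ["P2"] * 100)
        res = wc_fst(ds, "P1", "P2")
        assert res.genomewide_weighted > 0.99

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_oracle_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 11, size=2)
        m = int(rng.integers(1, 6))
        calls = rng.choice(
            [0, 1, 2, MISSING], size=(n1 + n2, m), p=[0.3, 0.3, 0.3, 0.1]
        ).astype(np.int8)
        ds = make_dataset(
            calls,
            positions=[1000 * (j + 1) for j in range(m)],
            breeds=["P1"] * n1 + ["P2"] * n2,
        )
        try:
            res = wc_fst(ds, "P1", "P2")
        except ValueError:
            return  # degenerate toy (no joint polymorphism): both routes undefined
        expected = oracle_weighted_fst(calls[:n1], calls[n1:])
        assert res.genomewide_weighted == pytest.approx(expected, abs=1e-10)

    def test_split_halves_of_one_breed_near_zero(self, three_breed_sim):
        ds, _ = three_breed_sim
        idx = ds.breed_indices("A")
        sub = ds.subset_samples(list(idx))
        sub.breed_labels = ["H1" if i % 2 == 0 else "H2" for i in range(len(idx))]
        res = wc_fst(sub, "H1", "H2")
        assert abs(res.genomewide_weighted) < 0.03

    def test_monomorphic_error(self):
        calls = np.zeros((8, 3), dtype=np.int8)
        ds = make_dataset(calls, breeds=["P1"] * 4 + ["P2"] * 4)
        with pytest.raises(ValueError):
            wc_fst(ds, "P1", "P2")


class TestConsensus:
    def test_majority_allele(self):
        ds = make_dataset(np.array([[2, 2, 2, 1, 0]]).T)  # f(b) = 0.7
        assert consensus_sequence(ds, "P1").symbols == "G"

    def test_tie_gives_iupac(self):
        ds = make_dataset(np.array([[0, 2]]).T)  # f = 0.5, alleles A/G
        assert consensus_sequence(ds, "P1").symbols == "R"

    def test_all_missing_gap(self):
        ds = make_dataset(np.array([[MISSING, MISSING]]).T)
        assert consensus_sequence(ds, "P1").symbols == "-"


class TestTajimaNei:
    def test_identical_zero(self):
        assert tajima_nei_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_equal_frequency_limit_matches_jukes_cantor(self):
        x, y = balanced_pair(p=0.1)
        d = tajima_nei_distance(x, y)
        assert d == pytest.approx(-0.75 * math.log(1 - 0.1 / 0.75), abs=1e-9)

    def test_pairwise_deletion_lowers_p(self):
        x, y = balanced_pair(p=0.1)
        # gap two differing sites in x: fewer differences survive deletion
        diff_sites = [i for i, (a, b) in enumerate(zip(x, y)) if a != b]
        x_gapped = list(x)
        for i in diff_sites[:2]:
            x_gapped[i] = "-"
        d_full = tajima_nei_distance(x, y)
        d_gapped = tajima_nei_distance("".join(x_gapped), y)
        assert d_gapped < d_full

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tajima_nei_distance("ACGT", "ACG")

    def test_no_joint_sites(self):
        with pytest.raises(ValueError):
            tajima_nei_distance("--", "AC")

    def test_saturation_error(self):
        x = "A" * 50 + "C" * 50
        y = "C" * 50 + "A" * 50
        with pytest.raises(ValueError, match="saturated"):
            tajima_nei_distance(x, y)


def balanced_pair(p=0.1, unit=10):
    """Two sequences with equal base composition whose differing sites cover
    all six substitution pair types evenly -> Tajima-Nei b = 3/4 exactly."""
    pairs = list(itertools.permutations("ACGT", 2))  # 12 directed pairs
    n_diff = len(pairs) * unit
    n_total = int(n_diff / p)
    n_same = n_total - n_diff
    assert n_same % 4 == 0
    x = [a for a, _ in pairs for _ in range(unit)]
    y = [b for _, b in pairs for _ in range(unit)]
    for base in "ACGT":
        x += [base] * (n_same // 4)
        y += [base] * (n_same // 4)
    return "".join(x), "".join(y)


class TestDistanceMatrix:
    def test_structure(self, three_breed_sim):
        ds, _ = three_breed_sim
        tn, fst = distance_matrix(ds)
        for dm in (tn, fst):
            assert dm.labels == ["A", "B", "C"]
            assert np.allclose(dm.values, dm.values.T)
            assert np.allclose(np.diag(dm.values), 0.0)

    def test_identical_breeds_near_zero(self):
        # keep frequencies away from 0.5 so consensus majority calls are
        # stable under sampling noise
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.1, 0.35, 200)
        calls = rng.binomial(2, freqs, size=(40, 200)).astype(np.int8)
        alleles = [tuple(rng.choice(list("ACGT"), 2, replace=False)) for _ in range(200)]
        ds = make_dataset(
            calls,
            positions=[1000 * (j + 1) for j in range(200)],
            breeds=["P1"] * 20 + ["P2"] * 20,
            alleles=alleles,
        )
        tn, fst = distance_matrix(ds)
        assert tn.get("P1", "P2") < 0.05
        assert abs(fst.get("P1", "P2")) < 0.02

    def test_table_layout(self, three_breed_sim):
        ds, _ = three_breed_sim
        tn, fst = distance_matrix(ds)
        table = fst_tn_table(tn, fst)
        assert table.loc["A", "A"] == "-"
        assert table.loc["B", "A"] == f"{fst.get('A', 'B'):.4f}"
        assert table.loc["A", "B"] == f"{tn.get('A', 'B'):.4f}"


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_taxa):
    """Random binary topology with uniform branch lengths; returns (dendropy
    tree, labels, distance matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        leaf = dendropy.Node()
        leaf.taxon = taxa.get_taxon(lab)
        nodes.append(leaf)
    rng.shuffle(nodes)
    while len(nodes) > 3:
        a = nodes.pop()
        b = nodes.pop()
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = round(rng.uniform(0.1, 1.0), 3)
        b.edge.length = round(rng.uniform(0.1, 1.0), 3)
        nodes.append(parent)
    for child in nodes:
        tree.seed_node.add_child(child)
        child.edge.length = round(rng.uniform(0.1, 1.0), 3)
    tree.update_bipartitions(suppress_unifurcations=False)
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        d[i, j] = d[j, i] = pdm.distance(
            taxa.get_taxon(labels[i]), taxa.get_taxon(labels[j])
        )
    return tree, labels, d


def edge_length_by_split(tree):
    """Map frozenset-of-leaf-labels (smaller side) -> branch length."""
    tree.update_bipartitions(suppress_unifurcations=False)
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.head_node is tree.seed_node:
            continue
        side = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        other = all_leaves - side
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        out[key] = out.get(key, 0.0) + edge.length
    return out


class TestNJ:
    def test_three_taxon_worked_case(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = nj_tree(dm)
        lengths = {
            child.label: length for child, length in tree.root.children
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_ultrametric_three_taxa_star(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        )
        tree = nj_tree(dm)
        assert [round(l, 9) for _, l in tree.root.children] == [1.0, 1.0, 1.0]

    def test_four_taxon_additive_exact(self):
        rng = np.random.Generator(np.random.PCG64(0))
        true_tree, labels, d = random_additive_tree(rng, 4)
        result = nj_tree(DistanceMatrix(labels, d))
        inferred = dendropy.Tree.get(
            data=result.newick(), schema="newick",
            taxon_namespace=true_tree.taxon_namespace,
        )
        expected = edge_length_by_split(true_tree)
        got = edge_length_by_split(inferred)
        assert set(got) == set(expected)
        for split, length in expected.items():
            assert got[split] == pytest.approx(length, abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_additive_recovery(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        n_taxa = int(rng.integers(6, 11))
        true_tree, labels, d = random_additive_tree(rng, n_taxa)
        result = nj_tree(DistanceMatrix(labels, d))
        inferred = dendropy.Tree.get(
            data=result.newick(), schema="newick",
            taxon_namespace=true_tree.taxon_namespace,
        )
        expected = edge_length_by_split(true_tree)
        got = edge_length_by_split(inferred)
        assert set(got) == set(expected)
        for split, length in expected.items():
            assert got[split] == pytest.approx(length, abs=1e-9)

    def test_newick_round_trip(self, three_breed_sim):
        ds, _ = three_breed_sim
        tn, _ = distance_matrix(ds)
        nwk = nj_tree(tn).newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == set(tn.labels)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    def test_too_few_taxa(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nj_tree(dm)
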