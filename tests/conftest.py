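from __future__ import annotations

import numpy as np
import pytest

from popchip.genotype_io import GenotypeDataset, SNPRecord
from popchip.simulate import BranchSpec, SimulationConfig, simulate_breeds


def make_dataset(calls, positions=None, chromosomes=None, breeds=None,
                 alleles=None):
    """Handcrafted dataset helper: ``calls`` is a (samples x snps) list/array
    with -1 for missing."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if chromosomes is None:
        chromosomes = ["1"] * m
    if breeds is None:
        breeds = ["P1"] * n
    if alleles is None:
        alleles = [("A", "G")] * m
    snps = [
        SNPRecord(f"snp{j + 1}", chromosomes[j], positions[j], *alleles[j])
        for j in range(m)
    ]
    return GenotypeDataset(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        breed_labels=list(breeds),
        snps=snps,
        calls=calls,
    )


@pytest.fixture(scope="session")
def three_breed_sim():
    """Moderate three-breed star split with missingness, shared across tests."""
    tree = BranchSpec(
        "root", 60, 5,
        [BranchSpec("A", 50, 20), BranchSpec("B", 50, 20), BranchSpec("C", 50, 20)],
    )
    config = SimulationConfig(
        tree=tree,
        n_chromosomes=2,
        n_snps_per_chrom=400,
        chrom_length_mb=80.0,
        samples_per_breed=15,
        missing_rate=0.01,
        seed=11,
    )
    return simulate_breeds(config)
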