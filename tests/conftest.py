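"""Shared fixtures: small synthetic studies and pedigree oracles."""

import numpy as np
import pytest

from rhizoherit.pedigree import Pedigree, additive_relationship
from rhizoherit.simulate import simulate_study, AsvSimParams


@pytest.fixture(scope="session")
def small_study():
    """A reduced trial: 10 families, 30 genotypes, 3 ramets, 24 ASVs."""
    return simulate_study(
        seed=20260915,
        n_founders=12,
        n_families=10,
        n_genotypes=30,
        progeny_per_family_range=(3, 6),
        ramets_per_genotype=3,
        block_capacity=16,
        asv_params=AsvSimParams(n_asvs=24, mean_depth=4000.0),
    )


@pytest.fixture(scope="session")
def study_design():
    """Full study-scale design (132 genotypes x 4 ramets) without counts."""
    return simulate_study(
        seed=20260916,
        asv_params=AsvSimParams(n_asvs=4),  # counts unused; keep it cheap
    )


@pytest.fixture(scope="session")
def nuclear_family_pedigree():
    """Two founder couples, full sibs, half sibs, and a full-sib mating."""
    return Pedigree((
        ("s1", None, None), ("d1", None, None), ("d2", None, None),
        ("fs_a", "s1", "d1"), ("fs_b", "s1", "d1"),   # full sibs
        ("hs_c", "s1", "d2"),                          # half sib of the above
        ("inbred", "fs_a", "fs_b"),                    # full-sib mating
    ))


def gene_drop_ibd(pedigree: Pedigree, n_rep: int, seed: int) -> np.ndarray:
    """Independent gene-dropping oracle for the additive relationship matrix.

    Founders receive uniquely labelled alleles; alleles drop through the
    pedigree by fair Mendelian sampling, replicated ``n_rep`` times. The
    empirical numerator relationship is twice the observed kinship: the
    average fraction of matching allele pairs between two individuals.
    Deliberately independent of the tabular-method implementation.
    """
    rng = np.random.default_rng(seed)
    ids = pedigree.ids
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    alleles = np.zeros((n, 2, n_rep), dtype=np.int32)
    next_label = 0
    for k, (i, s, d) in enumerate(pedigree.records):
        for a, parent in enumerate((s, d)):
            if parent is None:
                alleles[k, a] = next_label
                next_label += 1
            else:
                p = alleles[pos[parent]]
                pick = rng.integers(0, 2, size=n_rep)
                alleles[k, a] = p[pick, np.arange(n_rep)]
    A = np.zeros((n, n))
    for i in range(n):
        A[i, i] = 1.0 + (alleles[i, 0] == alleles[i, 1]).mean()
        for j in range(i + 1, n):
            match = sum(
                (alleles[i, a] == alleles[j, b]).mean() for a in (0, 1) for b in (0, 1)
            )
            A[i, j] = A[j, i] = match / 2.0
    return A


@pytest.fixture(scope="session")
def ibd_oracle():
    return gene_drop_ibd
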