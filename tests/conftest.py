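import numpy as np
import pytest

from hybnet.genotype_io import (
    GenotypeDataset,
    Individual,
    LocusGenotype,
    MISSING,
    SPIRALIS,
    VESICULOSUS,
)


def make_individual(ind_id, species, alleles, location="loc1", region="reg1",
                    hybrid_class=None):
    """Build an Individual from [(a1, a2) or None, ...] allele pairs."""
    genotype = tuple(
        MISSING if pair is None else LocusGenotype(*pair) for pair in alleles
    )
    return Individual(ind_id, species, location, region, genotype, hybrid_class)


def make_dataset(rows, loci=None):
    """rows: list of (id, species, [allele pairs]) or Individual."""
    individuals = [
        r if isinstance(r, Individual) else make_individual(r[0], r[1], r[2])
        for r in rows
    ]
    k = len(individuals[0].genotype)
    loci = loci or tuple(f"L{i+1}" for i in range(k))
    return GenotypeDataset(loci=tuple(loci), individuals=individuals)


def random_dataset(rng, n=10, k=3, missing_rate=0.0, species_split=True):
    rows = []
    for i in range(n):
        species = SPIRALIS if (species_split and i < n // 2) else VESICULOSUS
        alleles = []
        for _ in range(k):
            if missing_rate and rng.random() < missing_rate:
                alleles.append(None)
            else:
                alleles.append(tuple(100 + 2 * rng.integers(0, 8, size=2)))
        rows.append((f"ind_{i}", species, alleles))
    return make_dataset(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_dataset():
    return make_dataset(
        [
            ("a1", SPIRALIS, [(100, 104), (150, 150)]),
            ("a2", SPIRALIS, [(100, 100), (150, 154)]),
            ("b1", VESICULOSUS, [(120, 124), (170, 170)]),
            ("b2", VESICULOSUS, [(120, 120), (170, 174)]),
        ]
    )
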