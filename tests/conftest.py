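"""Shared fixtures: small hand-built datasets exercising mixed ploidy."""

import numpy as np
import pytest

from msatrelict.genodata import (
    Genotype,
    Individual,
    Locus,
    MsatDataset,
    Population,
)


def make_dataset(loci, pops, individuals):
    """Convenience constructor from plain tuples.

    ``individuals``: (id, pop, ploidy, {locus: alleles tuple}).
    """
    return MsatDataset(
        loci=[Locus(n, m) for n, m in loci],
        populations={c: Population(code=c, country=country)
                     for c, country in pops},
        individuals=[
            Individual(
                id=i, population=p, ploidy=pl,
                genotypes={k: Genotype(v) for k, v in g.items()},
            )
            for i, p, pl, g in individuals
        ],
    )


@pytest.fixture
def diploid_two_pop():
    """Two diploid populations, two dinucleotide loci, no missing data."""
    return make_dataset(
        loci=[("La", 2), ("Lb", 2)],
        pops=[("P1", "Tunisia"), ("P2", "Algeria")],
        individuals=[
            ("a1", "P1", 2, {"La": (100, 102), "Lb": (200, 200)}),
            ("a2", "P1", 2, {"La": (100, 100), "Lb": (200, 204)}),
            ("b1", "P2", 2, {"La": (102, 104), "Lb": (204, 204)}),
            ("b2", "P2", 2, {"La": (104, 104), "Lb": (200, 204)}),
        ],
    )


@pytest.fixture
def mixed_ploidy():
    """A tetraploid population alongside a diploid one."""
    return make_dataset(
        loci=[("La", 2), ("Lb", 2)],
        pops=[("TET", "Morocco"), ("DIP", "Tunisia")],
        individuals=[
            ("t1", "TET", 4, {"La": (100, 102, 104), "Lb": (200, 202, 204, 206)}),
            ("t2", "TET", 4, {"La": (100, 104), "Lb": (200, 200)}),
            ("d1", "DIP", 2, {"La": (100, 102), "Lb": (200, 204)}),
            ("d2", "DIP", 2, {"La": (102, 102), "Lb": (204, 204)}),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
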