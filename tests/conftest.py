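"""Shared fixtures: one small synthetic genome and its methylomes.

The session-scoped genome keeps the suite fast: most tests only need a
consistent world with planted truth, not their own simulation.
"""

import pytest

from epiphase.simulate import (
    GenomeSpec,
    GenotypeProfile,
    build_genome,
    simulate_methylome,
)

SMALL = dict(chromosome_length=300_000, te_count=20, gene_count=20)


@pytest.fixture(scope="session")
def small_genome():
    return build_genome(GenomeSpec(**SMALL), seed=11)


@pytest.fixture(scope="session")
def snapped_genome():
    return build_genome(GenomeSpec(**SMALL, snap_patches_to_grid=20), seed=11)


@pytest.fixture(scope="session")
def ddm1_methylome(small_genome):
    return simulate_methylome(small_genome, GenotypeProfile.ddm1(), seed=101)


@pytest.fixture(scope="session")
def ddm1clf_methylome(small_genome):
    return simulate_methylome(small_genome, GenotypeProfile.ddm1_clf(), seed=102)


@pytest.fixture(scope="session")
def wt_methylome(small_genome):
    return simulate_methylome(small_genome, GenotypeProfile.wt(), seed=103)


@pytest.fixture(scope="session")
def snapped_methylomes(snapped_genome):
    a = simulate_methylome(snapped_genome, GenotypeProfile.ddm1(), seed=201)
    b = simulate_methylome(snapped_genome, GenotypeProfile.ddm1_clf(), seed=202)
    return a, b
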