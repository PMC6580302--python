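import numpy as np
import pytest

from mesoped.genotype_data import (
    GenotypeTable,
    Individual,
    Locus,
    Origin,
    Tactic,
)


def make_table(genotypes_by_locus, origins=None, ids=None, flagged=()):
    """Build a GenotypeTable from {locus: [(a, b), ...]} dicts."""
    loci = list(genotypes_by_locus)
    n = len(next(iter(genotypes_by_locus.values())))
    if origins is None:
        origins = [Origin.SOUTH] * n
    if ids is None:
        ids = [f"I{i}" for i in range(n)]
    panel = [Locus(name, flagged_null=name in flagged) for name in loci]
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for l, name in enumerate(loci):
        for i, (a, b) in enumerate(genotypes_by_locus[name]):
            calls[i, l] = (a, b)
    individuals = [Individual(i_, o) for i_, o in zip(ids, origins)]
    return GenotypeTable(panel, individuals, calls)


def random_table(rng, n_ind=8, n_loci=2, n_alleles=3, n_pops=2,
                 missing_rate=0.0):
    """Random small table across pops for property tests."""
    panel = [Locus(f"L{l}") for l in range(n_loci)]
    origins_cycle = [Origin.SOUTH, Origin.WEST, Origin.OFFSPRING][:n_pops]
    individuals, rows = [], []
    # origin-grouped rows: the natural (POP-block) shape of the format
    order = sorted(range(n_ind), key=lambda i: i % n_pops)
    for i in order:
        origin = origins_cycle[i % n_pops]
        individuals.append(Individual(f"R{i}", origin))
        row = rng.integers(1, n_alleles + 1, size=(n_loci, 2))
        if missing_rate > 0:
            drop = rng.random(n_loci) < missing_rate
            row[drop] = 0
        rows.append(row)
    return GenotypeTable(panel, individuals, np.array(rows))


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration mesocosm simulation shared by the suite."""
    from mesoped.simulate import SimulationConfig, simulate_mesocosm

    return simulate_mesocosm(SimulationConfig(seed=7))


@pytest.fixture
def adult_registry():
    """A tiny two-origin adult registry with phenotypes."""
    adults = [
        Individual("M1", Origin.SOUTH, Tactic.NESTING_MALE, 14.0, 40.0),
        Individual("M2", Origin.WEST, Tactic.NESTING_MALE, 12.8, 30.0),
        Individual("S1", Origin.WEST, Tactic.SNEAKER_MALE, 12.3, 25.0),
        Individual("F1", Origin.SOUTH, Tactic.FEMALE, 14.4, 44.0),
        Individual("F2", Origin.WEST, Tactic.FEMALE, 12.9, 30.0),
    ]
    return {a.id: a for a in adults}
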