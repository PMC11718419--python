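import numpy as np
import pytest

from lynxrescue.genotypes import GenotypeDataset, GenotypeRecord, MarkerPanel
from lynxrescue.synthetic import generate_study_data


@pytest.fixture(scope="session")
def study():
    """Synthetic study system: two source populations, a drifted
    reintroduced population with longitudinal samples, recent translocants."""
    return generate_study_data(7)


@pytest.fixture(scope="session")
def dataset(study):
    return study["dataset"]


@pytest.fixture(scope="session")
def sources(study):
    return study["sources"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(rows, loci=("LocA", "LocB")):
    """Toy dataset from rows of (id, pop, year, sex, translocated, {locus: (a1,a2)|None})."""
    records = [
        GenotypeRecord(
            individual_id=r[0],
            population=r[1],
            date=str(r[2]) if r[2] is not None else None,
            sex=r[3],
            translocated=r[4],
            genotype=r[5],
        )
        for r in rows
    ]
    return GenotypeDataset(MarkerPanel(tuple(loci)), records)


def wright_fisher_sample(
    ne: int,
    n_sample: int,
    rng: np.random.Generator,
    n_loci: int = 19,
    n_alleles: int = 4,
    generations: int = 12,
) -> np.ndarray:
    """Independent oracle for LD-Ne: an ideal Wright-Fisher diploid
    population of constant size ``ne`` (random union of gametes, unlinked
    loci), sampled after ``generations`` rounds of drift.

    Returns an allele-call array (n_sample, n_loci, 2).
    """
    pop = rng.integers(0, n_alleles, size=(ne, n_loci, 2)).astype(np.int32)
    ar = np.arange(n_loci)
    for _ in range(generations):
        sires = rng.integers(0, ne, size=ne)
        dams = rng.integers(0, ne, size=ne)
        pick_s = rng.integers(0, 2, size=(ne, n_loci))
        pick_d = rng.integers(0, 2, size=(ne, n_loci))
        new = np.empty_like(pop)
        new[:, :, 0] = pop[sires[:, None], ar, pick_s]
        new[:, :, 1] = pop[dams[:, None], ar, pick_d]
        pop = new
    idx = rng.choice(ne, size=min(n_sample, ne), replace=False)
    return pop[idx]
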