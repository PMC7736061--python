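import numpy as np
import pytest

from strainassign import (
    GenotypeMatrix,
    PopulationSpec,
    SimDesign,
    make_fixture,
)


def random_matrix(rng, n_loci=None, n_samples=None, missing_frac=0.15):
    """Random valid GenotypeMatrix with missing calls sprinkled in."""
    n_loci = n_loci or int(rng.integers(1, 12))
    n_samples = n_samples or int(rng.integers(1, 10))
    calls = rng.integers(0, 3, size=(n_loci, n_samples)).astype(np.int16)
    drop = rng.random(calls.shape) < missing_frac
    calls[drop] = -1
    return GenotypeMatrix(
        [f"L{i}" for i in range(n_loci)],
        [f"S{j}" for j in range(n_samples)],
        calls,
    )


@pytest.fixture(scope="session")
def two_blob_fixture():
    """Two strongly diverged populations — effectively disjoint clusters."""
    design = SimDesign(
        n_loci=300,
        populations=[
            PopulationSpec("A", 40, f=0.5),
            PopulationSpec("B", 40, f=0.5),
        ],
        hatcheries=[],
        missing_rate=0.0,
        seed=42,
    )
    g, meta, truth = make_fixture(design)
    labels = meta.population_of().reindex(g.sample_ids).tolist()
    return g, meta, labels, truth


@pytest.fixture(scope="session")
def twin_population_fixture():
    """Two populations with identical allele frequencies plus one outgroup."""
    design = SimDesign(
        n_loci=400,
        populations=[
            PopulationSpec("A", 50, f=0.15),
            PopulationSpec("B", 50, f=0.0, admixture={"A": 1.0}),
            PopulationSpec("C", 50, f=0.15),
        ],
        hatcheries=[],
        missing_rate=0.0,
        seed=17,
    )
    g, meta, truth = make_fixture(design)
    labels = meta.population_of().reindex(g.sample_ids).tolist()
    return g, meta, labels, truth
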