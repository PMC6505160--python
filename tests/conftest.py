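import numpy as np
import pytest

import radpop as rp


@pytest.fixture(scope="session")
def structured():
    """Two clearly differentiated populations, some missing data."""
    params = rp.SimParams(seed=11, K=2, F=0.2, n_per_pop=25, n_loci=400,
                          missing_rate=0.05)
    gm, popmap, truth = rp.simulate_structured_population(params)
    return gm, popmap, truth


@pytest.fixture(scope="session")
def genome_fixture(tmp_path_factory):
    """Toy genome with planted motif sites, genes and heterochromatin."""
    out = tmp_path_factory.mktemp("genome")
    return rp.simulate_genome_fixture(out, seed=5)


@pytest.fixture()
def tiny_gm():
    """Hand-sized matrix for exact-value checks (no randomness)."""
    markers = [
        rp.MarkerInfo("chr1", 100, "A", "C"),
        rp.MarkerInfo("chr1", 150, "G", "T"),
        rp.MarkerInfo("chr1", 5000, "A", "G"),
    ]
    dosage = np.array(
        [
            [0, 0, 1],
            [1, 1, 2],
            [2, 2, 0],
            [0, 0, rp.MISSING],
        ],
        dtype=np.int8,
    )
    return rp.GenotypeMatrix(["a1", "a2", "a3", "a4"], markers, dosage)


def random_genotype_matrix(rng, n_acc=8, n_markers=12, missing_rate=0.1):
    markers = []
    pos = np.cumsum(rng.integers(1, 500, n_markers))
    for p in pos:
        ref, alt = rng.choice(list("ACGT"), 2, replace=False)
        markers.append(rp.MarkerInfo("chrZ", int(p), ref, alt))
    dosage = rng.integers(0, 3, (n_acc, n_markers))
    dosage = np.where(rng.random(dosage.shape) < missing_rate, rp.MISSING, dosage)
    ids = [f"s{i}" for i in range(n_acc)]
    return rp.GenotypeMatrix(ids, markers, dosage.astype(np.int8))
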