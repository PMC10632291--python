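import numpy as np
import pandas as pd
import pytest

import triqtl as tq


@pytest.fixture
def tiny_genotypes() -> tq.GenotypeMatrix:
    return tq.GenotypeMatrix(
        ["A", "B"], ["m1", "m2"], np.array([[1.0, -1.0], [-1.0, 1.0]]))


@pytest.fixture
def three_marker_map() -> tq.LinkageMap:
    return tq.LinkageMap(pd.DataFrame({
        "marker_id": ["m1", "m2", "m3"],
        "group": ["LG1", "LG1", "LG1"],
        "position_cM": [0.0, 10.0, 25.0],
    }))


@pytest.fixture(scope="session")
def sim_map() -> tq.LinkageMap:
    return tq.simulate_map(n_groups=3, markers_per_group=10, group_length_cM=90.0)


@pytest.fixture(scope="session")
def sim_population(sim_map):
    """A small simulated DH population with a known single-triple trait."""
    qtls = ("G1M004", "G2M005", "G3M006")
    arch = tq.Architecture(
        mean=50.0,
        additive={m: 5.0 for m in qtls},
        triples={qtls: 5.0},
        noise_sd=0.5, n_reps=3,
    )
    g = tq.simulate_genotypes(150, sim_map, seed=42)
    pheno = tq.simulate_phenotypes(g, arch, seed=43)
    return g, pheno, arch
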