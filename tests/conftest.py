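import numpy as np
import pandas as pd
import pytest

from hzkit.io_core import (GenotypeMatrix, ParentalFrequencies, SampleFrame,
                           TransplantTable)


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    return GenotypeMatrix(
        ["s1", "s2", "s3", "s4"],
        ["L0", "L1", "L2"],
        np.array([[2, 2, 2], [2, 2, 2], [0, 0, 0], [1, 1, -1]]),
    )


@pytest.fixture
def tiny_samples() -> SampleFrame:
    return SampleFrame(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "position": [120.0, 130.0, -120.0, 3.0],
        "habitat": ["dune", "dune", "desert", "ecotone"],
        "role": ["reference_P1", "reference_P1", "reference_P2", "query"],
    }))


@pytest.fixture
def divergent_freqs() -> ParentalFrequencies:
    f1 = np.array([0.9, 0.8, 0.9, 0.7])
    f2 = np.array([0.1, 0.2, 0.1, 0.3])
    return ParentalFrequencies(
        ["L0", "L1", "L2", "L3"], f1, f2,
        np.full(4, 40), np.full(4, 40))


def make_transplant(rows) -> TransplantTable:
    return TransplantTable(pd.DataFrame(
        rows, columns=["plant_id", "phenotype", "habitat", "water",
                       "survived", "biomass", "death_cause"]))


@pytest.fixture
def two_cell_transplant() -> TransplantTable:
    # one habitat, two phenotypes with cell composite means 2.0 and 0.5
    rows = []
    for i in range(4):
        rows.append([f"a{i}", "P1", "dune", "ambient", 1,
                     float(np.expm1(2.0)), "alive"])
        rows.append([f"b{i}", "P2", "dune", "ambient", 1,
                     float(np.expm1(0.5)), "alive"])
    return make_transplant(rows)
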