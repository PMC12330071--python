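import numpy as np
import pandas as pd
import pytest

import scplm
from scplm.pipeline import parse_variables


@pytest.fixture(scope="session")
def default_sim():
    """One simulated data set at the default study conditions."""
    return scplm.simulate(scplm.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def fitted(default_sim):
    """Model fit matching the generator's descriptors."""
    ds, truth = default_sim
    spec = scplm.ModelSpec(variables=parse_variables("run + label + celltype"))
    return ds, truth, scplm.fit_model(ds, spec)


@pytest.fixture()
def tiny_dataset():
    """A 3-peptide × 4-cell peptide-level log2 dataset, no missing values."""
    intensities = pd.DataFrame(
        [[7.0, 7.5, 6.5, 7.2], [8.0, 8.1, 7.9, 8.0], [5.0, 5.5, 5.2, 5.1]],
        index=["pepA", "pepB", "pepC"],
        columns=["c1", "c2", "c3", "c4"],
    )
    return scplm.ScpDataset(
        intensities=intensities,
        feature_annotations=pd.DataFrame(
            {"protein": ["P1", "P1", "P2"]}, index=intensities.index
        ),
        cell_annotations=pd.DataFrame(
            {"group": ["A", "A", "B", "B"]}, index=intensities.columns
        ),
        level="peptide",
        log_transformed=True,
    )
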