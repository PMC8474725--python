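import numpy as np
import pandas as pd
import pytest

from mirqpcr.normalization import NormalizedMatrix
from mirqpcr.plate_io import CtMatrix
from mirqpcr.synthetic_data import SimulationScenario, simulate_plates


def make_ct(values, samples, wells=None, plate_id="plate1"):
    """Build a CtMatrix from a 2-D array (NaN = not detected)."""
    values = np.asarray(values, dtype=float)
    wells = wells or [f"A{i + 1}" for i in range(values.shape[0])]
    index = pd.MultiIndex.from_arrays(
        [[plate_id] * len(wells), wells], names=["plate_id", "well_position"]
    )
    return CtMatrix(pd.DataFrame(values, index=index, columns=samples))


def make_nm(values, mirnas, samples):
    """NormalizedMatrix straight from an array, reference fixed at 0."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=mirnas, columns=samples)
    return NormalizedMatrix(values=df, reference_ct=pd.Series(0.0, index=df.columns))


@pytest.fixture(scope="session")
def clean_study():
    """Clean simulated study: planted effects but no QC failures expected."""
    scenario = SimulationScenario(seed=42)
    return simulate_plates(scenario)


@pytest.fixture(scope="session")
def study_with_rt_failure():
    scenario = SimulationScenario(seed=7, rt_fail_samples=("tumor_3",))
    return simulate_plates(scenario)
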