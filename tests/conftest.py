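import numpy as np
import pandas as pd
import pytest

from hippostress import synth


SMALL_N = {"TC1": 8, "TC2": 8, "TC3": 6, "RCC": 6}


@pytest.fixture(scope="session")
def small_config():
    return synth.SimulationConfig(
        n_per_cohort=dict(SMALL_N), n_timepoints_fmri=40, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synth.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def tabular_dataset():
    """Mid-size cohort without fMRI, for cortisol/contrast tests."""
    cfg = synth.SimulationConfig(
        n_per_cohort={"TC1": 25, "TC2": 25, "TC3": 15, "RCC": 15},
        with_fmri=False, seed=23,
    )
    return synth.simulate_cohort(cfg)


def make_saliva_profile(values_by_offset, subject_id="S1", timepoint="T0",
                        days=(1, 2)):
    """Long-format saliva rows with the same raw value on each day."""
    rows = []
    for day in days:
        for off, val in values_by_offset.items():
            rows.append((subject_id, timepoint, day, off, float(off), val))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "timepoint", "day", "offset_min",
                 "actual_min", "nmol_l"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
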