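import pytest

from needlehydro.hydraulics import compute_traits_table
from needlehydro.simulate import SimulationConfig, generate_dataset, study_calibration


@pytest.fixture(scope="session")
def study_dataset():
    """One simulated dataset at the field study's design (seed 1)."""
    return generate_dataset(SimulationConfig(seed=1), study_calibration())


@pytest.fixture(scope="session")
def traits_table(study_dataset):
    tracheids, needles = study_dataset
    return compute_traits_table(tracheids, needles)


@pytest.fixture(scope="session")
def degenerate_dataset():
    """Zero-dispersion dataset: every needle in a group is identical."""
    cfg = SimulationConfig(tree_cv=0, shoot_cv=0, diameter_cv=0, count_cv=0,
                           packing_cv=0, area_cv=0, flatness_excess_cv=0, seed=3)
    return generate_dataset(cfg, study_calibration())
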