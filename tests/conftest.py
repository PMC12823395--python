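import numpy as np
import pytest
from hypothesis import settings

from amide1.io import Spectrum, canonical_grid
from amide1.synthetic import CohortDesign, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return canonical_grid()


@pytest.fixture()
def quintic_spectrum(grid):
    """A degree-5 polynomial sampled on the canonical grid."""
    x = (grid.values - 1650.0) / 50.0
    y = 0.3 + 1.2 * x - 0.7 * x**2 + 0.5 * x**3 - 0.2 * x**4 + 0.11 * x**5
    return Spectrum(grid, y)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small noiseless cohort with planted responders, shared across tests."""
    design = CohortDesign(n_cells=6, time_points_h=(0.0, 48.0, 96.0),
                          responder_fraction=0.5, noise_sd=0.0,
                          amplitude_jitter=0.0, n_medium_spectra=2, seed=123)
    dataset, truth = simulate_cohort(design)
    return design, dataset, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The default study design cohort (shared; treat as read-only)."""
    dataset, truth = simulate_cohort(CohortDesign(seed=0))
    return dataset, truth
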