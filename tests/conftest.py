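import numpy as np
import pytest

from ktr.simulate import ImagingSpec, PopulationSpec, simulate_movie


@pytest.fixture(scope="session")
def small_imaging():
    # shortened schedule (10 min post-stimulation) keeps unit tests fast
    return ImagingSpec(duration_s=600.0, image_size=(200, 200), seed=11)


@pytest.fixture(scope="session")
def small_population():
    return PopulationSpec(
        n_cells=8,
        archetype_mix={"young": 0.5, "mid_old": 0.25, "old": 0.25},
        seed=7,
    )


@pytest.fixture(scope="session")
def movie_and_truth(small_population, small_imaging):
    """A noiseless, stationary 8-cell synthetic movie with ground truth."""
    return simulate_movie(small_population, small_imaging)
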