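import numpy as np
import pytest

from taupvc import run_subject
from taupvc.phantom import PhantomSpec, generate_phantom
from taupvc.volume_io import LabeledVolume, ScalarVolume, default_grid
from taupvc.reference_region import SuvrVolume


@pytest.fixture(scope="session")
def ideal_phantom():
    """Noiseless phantom with every off-target feature disabled."""
    spec = PhantomSpec(noise_sd=0.0).with_features(
        ech=False, bimodal_choroid=False, extracerebral_tissue=False)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def featured_phantom():
    """Noiseless phantom with hotspot, bimodal choroid and tissue activity."""
    return generate_phantom(PhantomSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def featured_config7(featured_phantom):
    return run_subject(*featured_phantom.pipeline_inputs(), config=7)


@pytest.fixture
def small_grid():
    return default_grid((20, 20, 20), 2.0)


def make_suvr(data, grid, reference_mean=1.0):
    return SuvrVolume(np.asarray(data, dtype=float), grid, reference_mean)


def make_labels(data, grid):
    return LabeledVolume(np.asarray(data, dtype=np.int32), grid)


def make_scalar(data, grid):
    return ScalarVolume(np.asarray(data, dtype=float), grid)
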