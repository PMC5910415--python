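import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from frapfit import synthetic as syn
from frapfit.rois import extract_curves
from frapfit.workflow import build_reference


@pytest.fixture(scope="session")
def disc_truth():
    """Ground truth of the standard 2D disc benchmark experiment."""
    return syn.SyntheticGroundTruth(D_true=50.0)


@pytest.fixture(scope="session")
def disc_dataset(disc_truth):
    return syn.generate_frap_dataset(disc_truth)


@pytest.fixture(scope="session")
def standard_rois(disc_truth):
    return syn._standard_rois(disc_truth)


@pytest.fixture(scope="session")
def disc_curves(disc_dataset, standard_rois):
    return extract_curves(disc_dataset.stack, [standard_rois["bleached"], standard_rois["slice"]])


@pytest.fixture(scope="session")
def disc_reference(disc_dataset, disc_truth, standard_rois):
    """Shared reference simulation for the standard disc experiment."""
    return build_reference(
        disc_dataset.stack.frames[0], disc_truth.build_geometry(), standard_rois
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
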