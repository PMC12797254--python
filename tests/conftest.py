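import numpy as np
import pytest

from taskoverlap.synthetic import (
    AcquisitionSpec,
    GroundTruth,
    make_block_design,
)


@pytest.fixture(scope="session")
def default_spec() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def small_spec() -> AcquisitionSpec:
    return AcquisitionSpec(grid_shape=(10, 10, 10))


def single_roi_truth(
    grid=(10, 10, 10),
    noise_sd=1.0,
    pattern_mean=1.0,
    pattern_sd=0.5,
    spatial_fwhm_mm=0.0,
    ar1=0.3,
    correlations=None,
    roi_slice=(slice(1, 9),) * 3,
) -> GroundTruth:
    """One cubic ROI covering the grid interior, all five conditions active."""
    mask = np.zeros(grid, dtype=bool)
    mask[roi_slice] = True
    if correlations is None:
        correlations = {
            frozenset({"Small", "Large"}): 0.6,
            frozenset({"Small", "Rhyme"}): 0.2,
            frozenset({"Large", "Rhyme"}): 0.5,
        }
    return GroundTruth(
        roi_masks={"roi": mask},
        condition_amplitudes={
            "Small": 2.0,
            "Large": 2.0,
            "PlusOne": 0.5,
            "Rhyme": 2.0,
            "LetterMatch": 0.5,
        },
        pattern_correlations=correlations,
        noise_sd=noise_sd,
        spatial_fwhm_mm=spatial_fwhm_mm,
        ar1_coefficient=ar1,
        pattern_mean=pattern_mean,
        pattern_sd=pattern_sd,
    )


@pytest.fixture(scope="session")
def roi_truth() -> GroundTruth:
    return single_roi_truth()


@pytest.fixture(scope="session")
def arithmetic_design(small_spec):
    return make_block_design("arithmetic", small_spec, seed=7)


@pytest.fixture(scope="session")
def rhyming_design(small_spec):
    return make_block_design("rhyming", small_spec, seed=7)
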