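import numpy as np
import pytest
from hypothesis import settings

from kinopipe.io import ArrayDesign, default_peptide_catalogue
from kinopipe.qc import chi2_consistency
from kinopipe.simulate import SimulationConfig, simulate
from kinopipe.vsn import apply_vsn, fit_vsn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> ArrayDesign:
    return ArrayDesign(default_peptide_catalogue(40), 5)


@pytest.fixture(scope="session")
def contrast_config() -> SimulationConfig:
    """One-tissue PCEP-vs-PBS dataset at full array scale."""
    return SimulationConfig(
        seed=1, groups=(("PBS", "MUSCLE", 5), ("PCEP", "MUSCLE", 5))
    )


@pytest.fixture(scope="session")
def contrast_dataset(contrast_config):
    return simulate(contrast_config)


@pytest.fixture(scope="session")
def normalized_contrast(contrast_dataset):
    spots, truth = contrast_dataset
    fit = fit_vsn(spots)
    return apply_vsn(spots, fit), truth, fit


@pytest.fixture(scope="session")
def contrast_consistency(normalized_contrast):
    norm, _, _ = normalized_contrast
    return chi2_consistency(norm)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
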