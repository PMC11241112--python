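import numpy as np
import pytest

from adcstab.features import ExtractionConfig
from adcstab.pipeline import RunConfig, run_pipeline
from adcstab.synthetic import PhantomConfig, generate_phantom


@pytest.fixture
def ext_config():
    return ExtractionConfig()


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom lesion (seeded)."""
    return generate_phantom(PhantomConfig(seed=7), case_id="fix7")


@pytest.fixture(scope="session")
def quiet_cohort_bundle():
    """Full pipeline result on a 30-lesion noise-free cohort.

    Shared by the parameter-recovery and top-feature checks so the cohort is
    extracted once per session.
    """
    import warnings

    cfg = RunConfig(
        n_lesions=30,
        cohort_seed=11,
        bootstrap_B=100,
        bootstrap_seed=1,
        phantom=PhantomConfig(noise_sigma=0.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


def random_levels(rng: np.random.Generator, shape=(7, 7), n_levels=4) -> np.ndarray:
    """A small discretized image with an irregular mask (0 = outside)."""
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return np.where(mask, levels, 0).astype(np.int64)
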