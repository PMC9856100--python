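import numpy as np
import pytest

from kidseg import phantoms, shape_prior


@pytest.fixture(scope="session")
def phantom_prior():
    """Shape prior built from a 30-mask phantom cohort (the study-scale cohort)."""
    spec = phantoms.PhantomSpec(seed=0)
    return shape_prior.build_prior(phantoms.generate_training_cohort(30, spec))


@pytest.fixture(scope="session")
def aligned_phantom():
    """One noisy phantom aligned with the prior frame, plus its ground truth."""
    spec = phantoms.PhantomSpec(seed=42)
    mask = phantoms.generate_kidney_mask(spec)
    img = phantoms.generate_dce_image(mask, spec)
    return img, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
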