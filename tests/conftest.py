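import numpy as np
import pytest

from gliotex.image import QuantizedROI, ROIMask, VolumeImage


def make_qroi(levels, n_levels=8, spacing=(1.0, 1.0, 1.0)) -> QuantizedROI:
    """QuantizedROI from an int array; 0 marks outside-mask voxels."""
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    if levels.ndim == 1:
        levels = levels[:, None, None]
    mask = ROIMask(levels > 0, spacing, role="tumor")
    return QuantizedROI(levels=levels, mask=mask, n_levels=n_levels, spacing_mm=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def phantom_patient():
    """One rendered default phantom (shared across tests for speed)."""
    from gliotex.phantom import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def phantom_features(phantom_patient):
    from gliotex.texture import extract_all

    volumes, tumors, nawm, _ = phantom_patient
    return extract_all(volumes, tumors, {m: nawm for m in volumes})
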