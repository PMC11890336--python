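import numpy as np
import pytest

from ushisto import PhantomSpec, generate_specimen_slice


def noise_free_spec(**overrides) -> PhantomSpec:
    base = dict(
        seed=1,
        shrinkage_factor=1.0,
        rotation_deg=0.0,
        translation_mm=(0.0, 0.0),
        landmark_jitter_sd_mm=0.0,
        annotation_noise_sd_mm=0.0,
        residual_deformation_amplitude_mm=0.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def noise_free_pair():
    """One fully noise-free identity-transform slice pair with truth."""
    return generate_specimen_slice(noise_free_spec(), 0, 0)


@pytest.fixture(scope="session")
def shrinkage_pair():
    """Zero-noise pair under the similarity transform (shrinkage 0.9, 10 deg, (3,1) mm)."""
    spec = noise_free_spec(
        shrinkage_factor=0.9, rotation_deg=10.0, translation_mm=(3.0, 1.0)
    )
    return generate_specimen_slice(spec, 0, 0)


def circle_mask(shape, center_px, radius_px):
    ii, jj = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((ii - center_px[0]) ** 2 + (jj - center_px[1]) ** 2 <= radius_px**2).astype(
        np.uint8
    )
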