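import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("deterministic")

from chromosep import (
    LesionSpec,
    MaskGeometry,
    Modality,
    PipelineConfig,
    RegionColorModel,
)

#: near-luminance-neutral unit direction used by the study generator
SEP_DIRECTION = np.array([0.8165, -0.4082, -0.4082])
SEP_DIRECTION /= np.linalg.norm(SEP_DIRECTION)


@pytest.fixture
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_geometry() -> MaskGeometry:
    # blob with area comfortably above the 2000-pixel sampling floor at 96x96
    return MaskGeometry(center=(0.5, 0.5), radii=(30.0, 28.0), irregularity=0.1)


def make_lesion_spec(cancer_mean=(160.0, 80.0, 80.0),
                     noncancer_mean=(130.0, 95.0, 95.0),
                     sd=10.0, image_size=(96, 96), seed=0,
                     gradient=0.0, geometry=None) -> LesionSpec:
    cov = (sd ** 2) * np.eye(3)
    if geometry is None:
        geometry = MaskGeometry(center=(0.5, 0.5), radii=(30.0, 28.0),
                                irregularity=0.1)
    return LesionSpec(
        lesion_id="L01", modality=Modality.WL,
        cancer_model=RegionColorModel(np.asarray(cancer_mean), cov),
        noncancer_model=RegionColorModel(np.asarray(noncancer_mean), cov),
        image_size=image_size, mask_geometry=geometry,
        luminance_gradient_amplitude=gradient, seed=seed)


def gaussian_sample_set(label, mean, n, seed, sd=12.0):
    """Directly drawn Gaussian RGB sample set (no image rendering)."""
    from chromosep.sampling import SampleSet

    rng = np.random.default_rng(seed)
    rgb = np.clip(rng.multivariate_normal(mean, (sd ** 2) * np.eye(3), size=n),
                  0, 255)
    lum = rgb @ np.array([0.299, 0.587, 0.114])
    return SampleSet(label, rgb, lum, np.zeros((n, 2), dtype=int))
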