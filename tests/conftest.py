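import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from spdri import (
    DetectorSpec,
    MCConfig,
    OpticalProperties,
    SourceSpec,
    TissueVolume,
    simulate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240424)


def uniform_volume(dims, props, n_media: int = 8) -> TissueVolume:
    """Homogeneous volume: every voxel the same medium (label 0)."""
    labels = np.zeros(dims, dtype=np.uint8)
    media = tuple(props for _ in range(n_media))
    return TissueVolume(labels=labels, voxel_size_um=1.0, media=media)


@pytest.fixture(scope="session")
def scattering_slab_run():
    """One cached transport through a homogeneous scattering slab.

    Matched refractive indices (no Fresnel), absorbing boundaries; reused by
    several transport tests to keep the suite fast.
    """
    props = OpticalProperties(mu_a=0.5, mu_s=10.0, g=0.8, n=1.0)
    labels = np.zeros((400, 400, 100), dtype=np.uint8)
    volume = TissueVolume(labels=labels, voxel_size_um=10.0,
                          media=tuple(props for _ in range(8)))
    detected = simulate(
        volume,
        SourceSpec(center=(200.0, 200.0), core_diameter_um=0.0,
                   numerical_aperture=1e-9),
        MCConfig(n_photons=40_000, seed=77, n_external=1.0),
        detector=DetectorSpec(numerical_aperture=1.0),
    )
    return volume, detected
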