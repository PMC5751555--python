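import numpy as np
import pytest

from nbds.color_features import default_gamut
from nbds.synthetic import ClassProfile, FaceSpec, generate_face


@pytest.fixture(scope="session")
def gamut():
    return default_gamut()


@pytest.fixture(scope="session")
def noiseless_face(gamut):
    """A face whose four regions are pure single-centroid colors."""
    spec = FaceSpec(
        region_mixtures={
            "FHB": np.eye(6)[0],
            "LCB": np.eye(6)[2],
            "RCB": np.eye(6)[3],
            "NBB": np.eye(6)[1],
        },
        sigma=0.0,
    )
    image, truth = generate_face(spec, seed=11, gamut=gamut)
    return image, truth


@pytest.fixture(scope="session")
def noisy_face(gamut):
    profile = ClassProfile(delta=0.4, sigma=0.02)
    spec = FaceSpec(
        region_mixtures={
            name: profile.base_mixture for name in ("FHB", "LCB", "RCB", "NBB")
        },
        sigma=profile.sigma,
    )
    image, truth = generate_face(spec, seed=5, gamut=gamut)
    return image, truth
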