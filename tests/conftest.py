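import numpy as np
import pytest

from panodent.model import MaskTransformer, ModelConfig
from panodent.phantom import PhantomConfig, generate_phantom

# study-scale desk conditions used across the suite: 64x128 phantoms with
# teeth spanning ~25-35% of image height, as in real panoramic radiographs
DESK_PHANTOM = dict(image_height=64, image_width=128, n_teeth=6,
                    tooth_size_range=(16.0, 22.0))

TINY_MODEL = dict(n_slots=12, feature_dim=32, n_decoder_stacks=1,
                  backbone_channels=(8, 16, 24, 32), embed_dim=16)


@pytest.fixture(scope="session")
def desk_sample():
    return generate_phantom(PhantomConfig(**DESK_PHANTOM, seed=3))


@pytest.fixture(scope="session")
def tiny_model():
    return MaskTransformer(ModelConfig(**TINY_MODEL, seed=0))


@pytest.fixture(scope="session")
def desk_output(tiny_model, desk_sample):
    return tiny_model.forward(desk_sample.image)


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
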