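import numpy as np
import pytest
from hypothesis import settings

import wheatcount as wc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """Width-reduced network shared by read-only tests."""
    return wc.assemble_model(wc.ModelConfig.tiny(seed=7))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """12 desk-scale synthetic ear-field images with manifest on disk."""
    outdir = tmp_path_factory.mktemp("fields")
    cfg = wc.SynthConfig.ear_field(image_size=128, count_mean=20.0,
                                   count_sd=8.0, count_min=0, count_max=45,
                                   seed=99)
    manifest = wc.generate_dataset(12, cfg, outdir)
    return outdir, cfg, manifest


def numerical_gradient(f, x, eps=1e-3):
    """Central finite differences of scalar-valued f wrt array x, in place."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
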