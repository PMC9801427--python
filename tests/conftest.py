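import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from desfold import synthetic
from desfold.sans import SASProfile


@pytest.fixture(scope="session")
def sphere_profile():
    """Sphere R = 30 A scattering profile with 1% multiplicative noise."""
    profile, truth = synthetic.gen_sans(
        components=[("sphere_monomer", 30.0, 1.0)], noise=(0.01, 1e-4), seed=3)
    return profile, truth


@pytest.fixture(scope="session")
def exact_guinier_profile():
    """Noise-free closed-form Guinier curve, rg = 23.24 A, I0 = 100."""
    q = np.linspace(1e-3, 0.12, 200)
    i = 100.0 * np.exp(-((q * 23.24) ** 2) / 3.0)
    return SASProfile(q, i, 0.01 * i)
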