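import numpy as np
import pytest

from paleoshape import LandmarkConfiguration, make_template


@pytest.fixture(scope="session")
def small_template():
    """Small bilaterally symmetric template: 20 fixed, 2x8 curve, 40 surface."""
    scheme, base = make_template(k_fixed=20, n_curves=2, curve_len=8, n_surface=40, seed=1)
    return scheme, base


@pytest.fixture(scope="session")
def tiny_template():
    scheme, base = make_template(k_fixed=12, n_curves=2, curve_len=6, n_surface=20, seed=2)
    return scheme, base


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_similarity(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random rotation, scaling and translation (never a reflection)."""
    from scipy.stats import special_ortho_group

    r = special_ortho_group.rvs(3, random_state=rng)
    s = rng.uniform(0.4, 2.5)
    t = rng.normal(scale=20.0, size=3)
    return coords @ r * s + t


def perturbed_configs(base: np.ndarray, n: int, sd: float, rng) -> list[LandmarkConfiguration]:
    return [
        LandmarkConfiguration(f"s{i}", base + rng.normal(scale=sd, size=base.shape))
        for i in range(n)
    ]
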