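import numpy as np
import pytest

from supertoroid.synthetic_phantom import (
    PhantomSpec,
    default_gradient_table,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        shape=(24, 24, 8), core_radius=4.0, edema_thickness=3.0, wm_halfwidth=2.5, seed=3
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def gradient_table():
    """32 directions at b=800 s/mm^2 plus one b=0, well-spread on the sphere."""
    return default_gradient_table(n_directions=32, b=800.0)


def random_sorted_eigenvalues(rng: np.random.Generator, n: int) -> np.ndarray:
    """n random nonnegative descending triples on a diffusivity-like scale."""
    lam = np.sort(rng.uniform(0.0, 3e-3, size=(n, 3)), axis=1)[:, ::-1]
    return lam
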