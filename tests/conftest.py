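import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrareg import mapk

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_connectivity(n: int, seed: int, density: float = 0.3) -> np.ndarray:
    """Random sparse connectivity matrix with -1 diagonal (test helper)."""
    rng = np.random.default_rng(seed)
    r = np.where(
        rng.random((n, n)) < density,
        rng.uniform(0.3, 2.0, (n, n)) * rng.choice([-1.0, 1.0], (n, n)),
        0.0,
    )
    np.fill_diagonal(r, -1.0)
    if np.linalg.cond(r) > 1e6:  # rare; redraw deterministically
        return random_connectivity(n, seed + 10_000, density)
    return r


@pytest.fixture(scope="session")
def kinase_model():
    return mapk.load_model()


@pytest.fixture(scope="session")
def kinase_basal(kinase_model):
    return mapk.steady_state(kinase_model)


@pytest.fixture(scope="session")
def kinase_exact(kinase_model, kinase_basal):
    return mapk.exact_connectivity(kinase_model, kinase_basal)


@pytest.fixture(scope="session")
def kinase_perturbed_states(kinase_model):
    """Shared cache of perturbed steady states, keyed by intensity."""
    return {}
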