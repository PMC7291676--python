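import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dvhrad import CumulativeDVH, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_uniform_dvh(dose: float, volume: float = 100.0, eps: float = 0.05, n_fractions: int = 33) -> CumulativeDVH:
    """Uniform-dose structure: full volume up to `dose`, zero just above."""
    return CumulativeDVH(
        "uniform",
        np.array([0.0, dose, dose + eps]),
        np.array([volume, volume, 0.0]),
        volume,
        n_fractions,
    )


def make_dvh(edges, volumes, label="s", n_fractions=33) -> CumulativeDVH:
    v = np.asarray(volumes, dtype=float)
    return CumulativeDVH(label, np.asarray(edges, dtype=float), v, float(v[0]), n_fractions)


def random_cumulative_dvh(rng: np.random.Generator, n_points: int | None = None) -> CumulativeDVH:
    """A random valid cumulative curve for property tests."""
    n = n_points or rng.integers(3, 40)
    edges = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 80.0, size=n - 1))])
    edges = np.unique(edges)
    drops = rng.random(edges.size)
    vol = 100.0 * np.concatenate([[1.0], 1.0 - np.cumsum(drops)[:-1] / drops.sum()])
    vol = np.clip(vol, 0.0, None)
    return CumulativeDVH("rand", edges, vol, 100.0, 33)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition 26-patient synthetic cohort, fixed seed."""
    return generate_cohort(n_patients=26, seed=20260920)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
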