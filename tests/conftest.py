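import numpy as np
import pytest

from megp import (
    MarkerMatrix,
    SimulationSpec,
    TrialData,
    linear_kernel,
    simulate_markers,
    simulate_trial,
    standardize,
)


@pytest.fixture(scope="session")
def small_markers() -> MarkerMatrix:
    return simulate_markers(12, 40, maf_range=(0.1, 0.5), seed=11)


@pytest.fixture(scope="session")
def small_kernel(small_markers):
    return linear_kernel(standardize(small_markers))


@pytest.fixture
def tiny_trial() -> TrialData:
    recs = [
        ("A", "E1", 1.0), ("B", "E1", 2.0), ("C", "E1", 3.0),
        ("A", "E2", 1.5), ("B", "E2", 2.5), ("C", "E2", 3.5),
    ]
    return TrialData(recs)


@pytest.fixture(scope="session")
def mdsl_sim():
    """A reusable small MDsl simulation with known truth."""
    spec = SimulationSpec(
        n_lines=60, n_markers=300, n_envs=3, model="MDsl",
        sigma2_g=0.6, sigma2_ge=0.4, sigma2_l=0.3, sigma2=1.0, seed=21,
    )
    T, truth = simulate_trial(spec)
    return spec, T, truth


def random_marker_matrix(rng: np.random.Generator, n: int, p: int) -> MarkerMatrix:
    X = rng.binomial(2, rng.uniform(0.1, 0.5, size=p)[None, :], size=(n, p)).astype(float)
    return MarkerMatrix([f"L{i}" for i in range(n)], X)
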