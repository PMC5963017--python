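import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_count_matrix(counts: np.ndarray, genotypes=None, doses=None,
                      tissue: str = "striatum"):
    """Tiny CountMatrix builder for unit tests."""
    from revsig import CountMatrix

    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "genotype": genotypes or ["WT"] * n_samples,
            "dose": doses or ["veh"] * n_samples,
            "tissue": tissue,
        },
        index=samples,
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)


@pytest.fixture
def small_cm():
    rng = np.random.default_rng(0)
    return make_count_matrix(rng.poisson(100, size=(50, 6)))


@pytest.fixture(scope="session")
def planted_run():
    """One planted-effect simulation with its disease/treatment DE results,
    shared across tests that only read it."""
    import revsig as rs

    cm, truth = rs.simulate_counts(rs.SimulationConfig(seed=42))
    de_a = rs.run_contrast(cm, "A")
    de_b = rs.run_contrast(cm, "B")
    return cm, truth, de_a, de_b
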