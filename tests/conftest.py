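import numpy as np
import pandas as pd
import pytest

from ecometrics import EcometricModel, WorldConfig, simulate_world


@pytest.fixture(scope="session")
def strong_world():
    """A moderately sized, strongly coupled synthetic study system."""
    return simulate_world(WorldConfig(seed=11, nx=36, ny=30, n_species=50))


@pytest.fixture(scope="session")
def strong_results(strong_world):
    summ = strong_world.summaries
    return {
        "MAT": EcometricModel(summ, env="MAT").fit(),
        "AP": EcometricModel(summ, env="AP").fit(),
    }


@pytest.fixture()
def random_summaries():
    """Unstructured community summaries for estimator-level tests."""
    rng = np.random.default_rng(42)
    n = 400
    mean = rng.uniform(0.5, 0.95, n)
    sd = rng.uniform(0.01, 0.25, n)
    mat = 20 * mean + rng.normal(0, 2, n)
    log_ap = 5 + 2 * sd * 4 + rng.normal(0, 0.3, n)
    return pd.DataFrame(
        {
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
            "richness": rng.integers(3, 12, n),
            "trait_mean": mean,
            "trait_sd": sd,
            "mat": mat,
            "ap": np.exp(log_ap),
            "log_ap": log_ap,
        },
        index=pd.RangeIndex(n, name="point_id"),
    )
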