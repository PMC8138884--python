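import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from paretomut import AlterationMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_matrix() -> AlterationMatrix:
    """Four samples, three genes: g1 in {s1,s2}, g2 in {s2,s3}, g3 in {s4}."""
    frame = pd.DataFrame(
        [[1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["g1", "g2", "g3"],
    )
    return AlterationMatrix(frame, "mutation")


def random_matrix(rng: np.random.Generator, n_samples=None, n_genes=None,
                  density=None) -> AlterationMatrix:
    n_samples = n_samples or int(rng.integers(2, 25))
    n_genes = n_genes or int(rng.integers(1, 10))
    density = density if density is not None else rng.uniform(0.05, 0.6)
    values = (rng.random((n_samples, n_genes)) < density).astype(np.int8)
    return AlterationMatrix(
        pd.DataFrame(
            values,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"g{j:02d}" for j in range(n_genes)],
        ),
        "mutation",
    )
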