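import numpy as np
import pandas as pd
import pytest

from ccrscan import BetaMatrix


@pytest.fixture
def small_matrix() -> BetaMatrix:
    """4 probes x 5 samples with one missing entry."""
    frame = pd.DataFrame(
        [
            [0.10, 0.90, 0.20, 0.50, 0.00],
            [0.90, 0.10, 0.80, np.nan, 1.00],
            [0.50, 0.50, 0.50, 0.50, 0.50],
            [0.05, 0.95, 0.15, 0.45, 0.05],
        ],
        index=["p1", "p2", "p3", "p4"],
        columns=["s1", "s2", "s3", "s4", "s5"],
    )
    return BetaMatrix(frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_beta_matrix(rng, n_probes=10, n_samples=20, null_rate=0.0) -> BetaMatrix:
    values = rng.random((n_probes, n_samples))
    if null_rate:
        values[rng.random(values.shape) < null_rate] = np.nan
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"p{i}" for i in range(n_probes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
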