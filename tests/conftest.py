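import numpy as np
import pandas as pd
import pytest

from tbipanel.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default synthetic cohort (seeded, shared across the session)."""
    return generate_cohort(default_config(seed=20210))


@pytest.fixture(scope="session")
def main_cohort(default_cohort) -> pd.DataFrame:
    """CT-positive patients only (the main analysis group)."""
    return default_cohort[default_cohort["ct_positive"]].reset_index(drop=True)


def random_toy_cohort(rng: np.random.Generator, n: int = 12, n_markers: int = 3):
    """Small random cohort + labels for brute-force oracle comparisons."""
    while True:
        y = (rng.random(n) < 0.5).astype(int)
        if 0 < y.sum() < n:
            break
    data = {f"m{j}": np.round(rng.normal(size=n), 3) for j in range(n_markers)}
    return pd.DataFrame(data), y
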