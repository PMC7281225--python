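import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# property tests replay the same example sequence on every run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from immunocyt import (
    APOBEC3_PANEL,
    CHECKPOINT_PANEL,
    ExpressionMatrix,
    default_config,
    generate_cohort,
)


def make_expression(values: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from {gene: per-sample TPM}."""
    return ExpressionMatrix(
        pd.DataFrame(values, index=samples).T.astype(float)
    )


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 samples with all score genes present at hand-pickable TPM values."""
    samples = ["A", "B", "C"]
    values = {"GZMA": [4.0, 1.0, 0.0], "PRF1": [9.0, 1.0, 5.0]}
    for g in APOBEC3_PANEL.members:
        values[g] = [1.0, 0.0, 3.0]
    for g in CHECKPOINT_PANEL.members:
        values[g] = [1.0, 1.0, 1.0]
    values["HLA-A"] = [10.0, 20.0, 30.0]
    values["HLA-B"] = [2.0, 4.0, 6.0]
    return make_expression(values, samples)


@pytest.fixture(scope="session")
def hot_cohort():
    """One standard synthetic cohort (n=400) with the default planted effects."""
    return generate_cohort(default_config(n_samples=400, seed=3))


def two_group_exponential(seed: int, n: int = 2000, hr: float = 0.5,
                          event_rate: float = 0.05, censor_rate: float = 0.01):
    """Two-arm exponential survival data with true hazard ratio ``hr``."""
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, n).astype(float)
    t_event = rng.exponential(1.0 / (event_rate * np.exp(np.log(hr) * group)))
    t_censor = rng.exponential(1.0 / censor_rate, n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return time, event, pd.DataFrame({"group": group})
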