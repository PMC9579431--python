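import numpy as np
import pandas as pd
import pytest

from akiphen import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def small_model_data():
    """Small preprocessed design + binary outcome for model-level tests."""
    rng = np.random.default_rng(5)
    n = 400
    X = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "b1": (rng.random(n) < 0.4).astype(float),
    })
    eta = -0.3 + 1.2 * X["x1"] - 0.8 * X["b1"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y.to_numpy()
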