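import numpy as np
import pandas as pd
import pytest

from myelindev import gam, synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def saturating_fit():
    """One REML fit of a noisy saturating trajectory (shared, read-only)."""
    rng = np.random.default_rng(7)
    age = rng.uniform(5, 35, 150)
    sex = rng.choice(["F", "M"], 150)
    params = synthetic.GrowthParams(1.2, 0.6, rate=np.log(100) / 7.5)
    y = synthetic.growth_curve(params, age) + rng.normal(0, 0.06, 150)
    fit = gam.fit_gam(pd.DataFrame({"age": age, "value": y, "sex": sex}))
    return fit, params


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic small human cohort with ground truth."""
    return synthetic.simulate_cohort(20, 6, 3, seed=99)
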