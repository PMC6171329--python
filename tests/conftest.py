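import numpy as np
import pytest

from ezscore.survival import SurvivalData


def make_cohort(n, seed, hazard=0.03, censor_max=60.0, x_dist="lognormal"):
    """Random right-censored cohort with an independent covariate."""
    rng = np.random.default_rng(seed)
    if x_dist == "lognormal":
        x = rng.lognormal(5.0, 1.0, n)
    else:
        x = rng.normal(0.0, 1.0, n)
    t = rng.exponential(1.0 / hazard, n)
    c = rng.uniform(0.0, censor_max, n)
    surv = SurvivalData(
        time=np.minimum(t, c),
        event=(t <= c).astype(int),
        sample_id=np.array([f"s{i}" for i in range(n)]),
    )
    return x, surv


@pytest.fixture
def null_cohort():
    return make_cohort(50, seed=7)


@pytest.fixture
def signature_params():
    from ezscore.io import load_signature_params

    return load_signature_params()
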