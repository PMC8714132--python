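import numpy as np
import pytest

import pairrisk as pr


def make_censored_dataset(rng, n=60, p=3, tie_prob=0.3):
    """Random censored survival data with day-resolution ties."""
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=0.5, size=p)
    t = rng.exponential(30.0 / np.exp(X @ beta))
    c = rng.exponential(60.0, n)
    time = np.ceil(np.minimum(t, c))  # integer days force ties
    if rng.random() < tie_prob:
        time = np.ceil(time / 3)  # heavier ties
    event = (t <= c).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return X, np.maximum(time, 1.0), event


@pytest.fixture(scope="session")
def demo_cohort():
    """Small seeded cohort with planted structure, shared across tests."""
    spec = pr.CohortSpec(n_tumor=200, n_normal=25, seed=11)
    expr, annot, surv, truth = pr.generate_cohort(spec)
    return spec, expr, annot, surv, truth


@pytest.fixture(scope="session")
def recovery_spec():
    """The parameter-recovery study design: 400 tumors, 3 planted pairs with
    |beta| >= 1 among a large stable candidate set, 30% censoring."""
    return pr.CohortSpec(
        n_tumor=400,
        n_normal=32,
        n_autophagy_mrna=24,
        n_lnc_linked=40,
        n_de_lnc=24,
        censor_rate=0.3,
    )
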