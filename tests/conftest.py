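import numpy as np
import pytest

import sinesurv as sv

# one representative parameter set per baseline family
FAMILY_GRID = [
    ("exponential", (1.0,)),
    ("exponential", (0.3,)),
    ("weibull", (1.0, 2.0)),
    ("weibull", (0.34, 0.95)),
    ("lomax", (1.0, 1.0)),
    ("lomax", (0.455, 0.376)),
    ("exponentiated_exponential", (0.5, 1.4)),
    ("exponentiated_exponential", (0.35, 1.04)),
    ("gompertz", (0.2, 1.0)),
    ("gompertz", (0.5, 0.8)),
]

FAMILY_IDS = [f"{fam}{args}" for fam, args in FAMILY_GRID]


@pytest.fixture(params=FAMILY_GRID, ids=FAMILY_IDS)
def sine_dist(request):
    fam, args = request.param
    return sv.make_sine(fam, *args)


@pytest.fixture(scope="session")
def toy_dataset():
    """Small fixed right-censored dataset with one binary covariate."""
    rng = np.random.default_rng(2024)
    n = 8
    return sv.SurvivalDataset(
        time=rng.exponential(2.0, n).round(3),
        event=np.array([1, 0, 1, 1, 0, 1, 1, 0]),
        covariates=np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)[:, None],
        covariate_names=["treatment"],
    )


@pytest.fixture(scope="session")
def gastric_fit():
    """One Bayesian fit of the gastric-like synthetic trial, shared across tests."""
    dataset, truth = sv.generate_synthetic_trial("gastric-like", seed=3)
    model = sv.SineGPH.from_dataset(dataset, family="weibull")
    results = model.fit_bayes(
        mcmc=sv.McmcConfig(chains=4, iterations=1200, warmup=600, seed=11)
    )
    return dataset, truth, results
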