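import numpy as np
import pytest

from doublecox import (DoubleCoxParams, FitOptions, ModelSpec,
                       SimulationConfig, draw_dataset, fit_ml)

# baseline truths used throughout the simulation benchmarks
WEIBULL_TRUTH = DoubleCoxParams(a=20.0, b=1.5, beta_scale=[0.5, 1.0],
                                beta_shape=[0.05, 0.1], sigma2=1.0)
GOMPERTZ_TRUTH = DoubleCoxParams(a=1e-4, b=0.1, beta_scale=[0.5, 1.0],
                                 beta_shape=[0.05, 0.1], sigma2=1.0)


@pytest.fixture(scope="session")
def weibull_truth():
    return WEIBULL_TRUTH


@pytest.fixture(scope="session")
def gompertz_truth():
    return GOMPERTZ_TRUTH


@pytest.fixture(scope="session")
def gompertz_dataset():
    """Moderate Gompertz dataset with frailty, shared across test modules."""
    cfg = SimulationConfig(family="gompertz", truth=GOMPERTZ_TRUTH,
                           N=800, Ncl=80, p_cens=0.0, p_Success=0.25, seed=101)
    return draw_dataset(cfg), cfg.model_spec()


@pytest.fixture(scope="session")
def gompertz_fit(gompertz_dataset):
    ds, spec = gompertz_dataset
    fit = fit_ml(ds, spec, FitOptions(multistart=1, seed=0))
    assert fit.converged
    return fit


def random_small_dataset(rng, max_n=20):
    """Tiny random clustered dataset for likelihood cross-checks."""
    from doublecox import SurvivalDataset
    n = int(rng.integers(3, max_n + 1))
    ncl = int(rng.integers(1, max(2, n // 2) + 1))
    return SurvivalDataset(
        time=rng.exponential(10.0, n) + 0.01,
        event=rng.integers(0, 2, n),
        cluster=rng.integers(0, ncl, n),
        covariates={"x1": rng.normal(size=n),
                    "x2": rng.integers(0, 2, n).astype(float)})


def random_params(rng):
    return DoubleCoxParams(
        a=float(rng.uniform(0.5, 30.0)), b=float(rng.uniform(0.2, 2.0)),
        beta_scale=rng.normal(0.0, 0.5, 2), beta_shape=rng.normal(0.0, 0.1, 1),
        sigma2=float(rng.uniform(0.1, 5.0)))
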