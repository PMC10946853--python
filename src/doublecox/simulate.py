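"""Synthetic clustered survival data from the double-Cox frailty model.

The generator mirrors the design used for the model's simulation benchmarks:
a binary covariate ``Success`` ~ Bernoulli(p_Success) and a continuous
``Score`` ~ Normal(0, 0.2) (variance, not SD), a shared gamma frailty per
cluster, event times by inversion of the conditional cumulative hazard
against unit-exponential draws, and uniform Uniform(0, theta) censoring whose
upper bound theta is calibrated by Monte Carlo so the population censoring
probability equals a requested rate ``p_cens``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import optimize

from .model import DoubleCoxParams, ModelFamily, ModelSpec, SurvivalDataset

__all__ = [
    "SimulationConfig",
    "FrailtyDraw",
    "sample_covariates",
    "sample_frailty",
    "inverse_cumulative_hazard",
    "calibrate_theta",
    "draw_dataset",
    "NO_CENSORING",
]

#: sentinel returned by calibrate_theta when p_cens = 0
NO_CENSORING = math.inf

_EXP_CLIP = 700.0


@dataclass
class SimulationConfig:
    """One simulation scenario: family, truth and data-structure parameters.

    ``score_mean``/``score_variance`` parameterize the continuous covariate
    (defaults 0 and 0.2); ``Nsim_calibration`` is the Monte-Carlo sample size
    for the censoring-bound calibration.
    """

    family: ModelFamily
    truth: DoubleCoxParams
    N: int
    Ncl: int
    p_cens: float = 0.0
    p_Success: float = 0.5
    score_mean: float = 0.0
    score_variance: float = 0.2
    Nsim_calibration: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        self.family = ModelFamily(self.family)
        if not (self.N >= self.Ncl >= 1):
            raise ValueError("need N >= Ncl >= 1")
        if not (0.0 <= self.p_cens < 1.0):
            raise ValueError("p_cens must lie in [0, 1)")
        if not (0.0 <= self.p_Success <= 1.0):
            raise ValueError("p_Success must lie in [0, 1]")
        if self.score_variance <= 0:
            raise ValueError("score_variance must be positive")

    def model_spec(self) -> ModelSpec:
        """ModelSpec with covariate lists matching the truth's coefficients."""
        names = ("Success", "Score")
        return ModelSpec(
            family=self.family,
            scale_covariates=names[: self.truth.beta_scale.size],
            shape_covariates=names[: self.truth.beta_shape.size])

    def to_json(self) -> str:
        d = asdict(self)
        d["family"] = self.family.value
        d["truth"] = dict(a=self.truth.a, b=self.truth.b,
                          beta_scale=list(self.truth.beta_scale),
                          beta_shape=list(self.truth.beta_shape),
                          sigma2=self.truth.sigma2)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["truth"] = DoubleCoxParams(**d["truth"])
        return cls(**d)


@dataclass(frozen=True)
class FrailtyDraw:
    """Cluster-level frailty values and their logs (the 'random effects')."""

    z: np.ndarray
    log_z: np.ndarray = field(init=False)

    def __post_init__(self):
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if np.any(z <= 0):
            raise ValueError("frailty values must be positive")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "log_z", np.log(z))


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_covariates(N: int, p_Success: float, score_mean: float = 0.0,
                      score_variance: float = 0.2, seed=0):
    """Independent Success ~ Bernoulli(p) and Score ~ Normal(mean, variance)."""
    rng = _rng(seed)
    success = rng.binomial(1, p_Success, size=N).astype(float)
    score = rng.normal(score_mean, math.sqrt(score_variance), size=N)
    import pandas as pd
    return pd.DataFrame({"Success": success, "Score": score})


def sample_frailty(Ncl: int, sigma2: float, seed=0) -> FrailtyDraw:
    """Shared gamma frailty, mean 1, variance sigma2 (all ones at sigma2=0)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0:
        return FrailtyDraw(np.ones(Ncl))
    rng = _rng(seed)
    return FrailtyDraw(rng.gamma(shape=1.0 / sigma2, scale=sigma2, size=Ncl))


def inverse_cumulative_hazard(family, params: DoubleCoxParams, u, z, e):
    """The unique t with z * H(t|u) = e (vectorized over subjects).

    ``u`` is an (N, p_s + p_h) covariate block ordered (scale, shape); ``e``
    are positive exponential draws; ``z`` the per-subject frailty values.
    """
    family = ModelFamily(family)
    u = np.atleast_2d(np.asarray(u, dtype=float))
    z = np.asarray(z, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0) or np.any(z <= 0):
        raise ValueError("exponential draws and frailties must be positive")
    ps = params.beta_scale.size
    eta_s = u[:, :ps] @ params.beta_scale if ps else 0.0
    eta_h = u[:, ps:] @ params.beta_shape if params.beta_shape.size else 0.0
    B = params.b * np.exp(eta_h)
    core = e / (z * np.exp(np.minimum(eta_s, _EXP_CLIP)))
    if family is ModelFamily.WEIBULL:
        t = np.power(params.a * core, 1.0 / B)
    else:
        t = np.log1p(B * core / params.a) / B
    return t


def _covariate_block(config: SimulationConfig, cov) -> np.ndarray:
    """(scale columns | shape columns) block in coefficient order."""
    spec = config.model_spec()
    us = cov[list(spec.scale_covariates)].to_numpy(dtype=float)
    uh = cov[list(spec.shape_covariates)].to_numpy(dtype=float)
    return np.hstack([us, uh])


def _draw_event_times(config: SimulationConfig, rng: np.random.Generator,
                      n: int, fresh_frailty_per_subject: bool):
    """n event times from the full generative model (no censoring)."""
    cov = sample_covariates(n, config.p_Success, config.score_mean,
                            config.score_variance, rng)
    u = _covariate_block(config, cov)
    if fresh_frailty_per_subject:
        z = sample_frailty(n, config.truth.sigma2, rng).z
    else:
        z = np.ones(n)
    e = rng.exponential(1.0, size=n)
    return inverse_cumulative_hazard(config.family, config.truth, u, z, e)


def calibrate_theta(config: SimulationConfig, seed=None) -> float:
    """Upper bound theta of the Uniform(0, theta) censoring distribution.

    For C ~ Uniform(0, theta) independent of the event time T, the censoring
    probability is  p(theta) = E[P(C < T | T)] = E[min(T, theta)] / theta,
    estimated on a fixed Monte-Carlo sample of ``Nsim_calibration`` event
    times drawn from the full generative model (covariates and frailty
    marginalized with fresh draws).  Common random numbers make p(theta)
    smooth and strictly decreasing, so the root of p(theta) = p_cens is found
    by bracketed root finding.  Returns the NO_CENSORING sentinel (inf) when
    p_cens = 0.
    """
    if config.p_cens == 0:
        return NO_CENSORING
    rng = _rng(config.seed if seed is None else seed)
    T = _draw_event_times(config, rng, config.Nsim_calibration,
                          fresh_frailty_per_subject=True)

    def p_minus_target(theta):
        return float(np.minimum(T, theta).mean()) / theta - config.p_cens

    lo = hi = float(np.median(T))
    while p_minus_target(lo) < 0:   # p too small -> shrink theta
        lo /= 8.0
    while p_minus_target(hi) > 0:   # p too large -> grow theta
        hi *= 8.0
        if hi > 1e12:
            raise RuntimeError("censoring calibration failed to bracket a root")
    return float(optimize.brentq(p_minus_target, lo, hi, xtol=1e-12, rtol=1e-14))


def draw_dataset(config: SimulationConfig, seed=None,
                 theta: Optional[float] = None) -> SurvivalDataset:
    """One replication: clustered, possibly censored, double-Cox data.

    Subjects are allocated to ``Ncl`` clusters in equal contiguous blocks
    (any remainder goes to the first clusters).  Each subject's event time
    inverts z * H(t|u) = e with the cluster's shared frailty z and a
    unit-exponential draw e; censoring times are Uniform(0, theta), with
    theta calibrated on the fly (from this config's seed) when censoring is
    requested but no theta is supplied.
    """
    rng = _rng(config.seed if seed is None else seed)
    N, Ncl = config.N, config.Ncl
    base, extra = divmod(N, Ncl)
    sizes = np.full(Ncl, base) + (np.arange(Ncl) < extra)
    cluster = np.repeat(np.arange(Ncl), sizes)

    cov = sample_covariates(N, config.p_Success, config.score_mean,
                            config.score_variance, rng)
    frailty = sample_frailty(Ncl, config.truth.sigma2, rng)
    z = frailty.z[cluster]
    e = rng.exponential(1.0, size=N)
    T = inverse_cumulative_hazard(config.family, config.truth,
                                  _covariate_block(config, cov), z, e)
    if config.p_cens > 0:
        if theta is None:
            theta = calibrate_theta(config)
        C = rng.uniform(0.0, theta, size=N)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(N, dtype=int)
    # guard against zero times from underflow in extreme draws
    time = np.maximum(time, 1e-300)
    return SurvivalDataset(time, event, cluster, cov)
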