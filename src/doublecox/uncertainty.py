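"""Interval estimation for the double-Cox frailty model.

Three interval methods are provided:

* **Wald** — estimate +/- z * SE from the inverse observed information, with
  the baseline parameters a and b handled on the log scale (intervals are
  back-transformed by exponentiation) and regression coefficients on the
  natural scale.
* **Boundary mixture** — for the frailty variance, whose estimate can sit on
  the boundary sigma2 = 0, the limit law is a mixture of a truncated normal
  and a point mass at zero.  With plug-in weights the mixture CDF collapses
  to a normal CDF truncated at zero, so the interval is a Wald interval
  clipped below at 0; the full mixture CDF/quantile pair is exposed for
  verification.
* **Profile likelihood** — endpoints solve 2*(l_max - l_profile(v)) = q with
  q the chi-square(1) quantile (3.84 at 95%), the profile re-maximizing over
  all remaining parameters (sigma2 kept >= 0) with warm starts.

Observed information is a central-difference Hessian of the negative marginal
log-likelihood on the mixed reporting scale (ln a, ln b, betas, sigma2),
computed with per-coordinate steps and a one-sided scheme for coordinates at
their bound, inverted with a pseudo-inverse fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .estimation import FitOptions, FitResult, _bounds, _maximize, _pack, _unpack
from .likelihood import LoglikData
from .model import DoubleCoxParams, ModelSpec, SurvivalDataset

__all__ = [
    "InformationMatrix",
    "ConfidenceInterval",
    "CoverageEstimate",
    "numerical_hessian",
    "observed_information",
    "wald_ci",
    "sigma2_boundary_ci",
    "mixture_cdf",
    "mixture_quantile",
    "profile_ci",
    "coverage_probability",
    "CHI2_95_1DF",
]

#: likelihood-ratio inversion constant for a 95% interval on one parameter
CHI2_95_1DF = float(stats.chi2.ppf(0.95, 1))


@dataclass
class InformationMatrix:
    """Inverse observed information on the reporting scale.

    ``covariance`` estimates Cov(xi_hat) for xi = (ln a, ln b, betas, sigma2);
    ``kappa`` is the scale of the asymptotic sqrt(N)-normalized sigma2
    component, kappa = sqrt(N * covariance[s, s]), feeding the boundary
    mixture.  ``reliable`` is False when the Hessian was singular or
    indefinite and a pseudo-inverse was used.
    """

    covariance: np.ndarray
    kappa: float
    k: int
    names: tuple
    n: int
    reliable: bool = True

    @property
    def matrix(self) -> np.ndarray:
        return self.covariance

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return math.sqrt(max(self.covariance[i, i], 0.0))


@dataclass(frozen=True)
class ConfidenceInterval:
    parameter: str
    lower: float
    upper: float
    level: float
    method: str
    reliable: bool = True

    def __post_init__(self):
        if self.lower > self.upper + 1e-12:
            raise ValueError("interval endpoints out of order")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class CoverageEstimate:
    """Fraction of replications covering the truth, with binomial SE."""

    value: float
    se: float
    n: int

    def __float__(self) -> float:
        return self.value


def numerical_hessian(f, x, steps=None, lower_bounds=None) -> np.ndarray:
    """Central-difference Hessian with per-coordinate steps.

    Coordinates sitting at a lower bound are differenced on a grid shifted
    into the feasible region (one-sided), so the Hessian is still defined at
    a boundary optimum.  The result is symmetrized.
    """
    x = np.asarray(x, dtype=float)
    k = x.size
    if steps is None:
        steps = 1e-4 * np.maximum(np.abs(x), 0.1)
    steps = np.asarray(steps, dtype=float)
    lb = np.full(k, -np.inf) if lower_bounds is None else np.asarray(lower_bounds, dtype=float)
    # shift the evaluation center so x_i - h_i stays feasible
    center = x.copy()
    for i in range(k):
        if center[i] - steps[i] < lb[i]:
            center[i] = lb[i] + steps[i]

    H = np.empty((k, k))
    f0 = f(center)
    for i in range(k):
        ei = np.zeros(k); ei[i] = steps[i]
        H[i, i] = (f(center + ei) - 2.0 * f0 + f(center - ei)) / steps[i] ** 2
        for j in range(i):
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(center + ei + ej) - f(center + ei - ej)
                - f(center - ei + ej) + f(center - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return 0.5 * (H + H.T)


def _report_vector(params: DoubleCoxParams) -> np.ndarray:
    return np.concatenate([[math.log(params.a), math.log(params.b)],
                           params.beta_scale, params.beta_shape,
                           [params.sigma2]])


def _params_from_report(x, ps, ph) -> Optional[DoubleCoxParams]:
    if x[-1] < 0:
        return None
    return DoubleCoxParams(a=math.exp(x[0]), b=math.exp(x[1]),
                           beta_scale=np.asarray(x[2:2 + ps]),
                           beta_shape=np.asarray(x[2 + ps:2 + ps + ph]),
                           sigma2=float(x[-1]))


def observed_information(dataset: SurvivalDataset, spec: ModelSpec,
                         params: DoubleCoxParams,
                         richardson: bool = False) -> InformationMatrix:
    """Inverse observed information at (or near) the maximum.

    ``richardson`` applies one step-halving extrapolation to the Hessian
    (used as an internal accuracy cross-check; the plain central-difference
    Hessian is the default).
    """
    data = LoglikData(dataset, spec)
    ps, ph = len(spec.scale_covariates), len(spec.shape_covariates)
    x_hat = _report_vector(params)
    lb = np.full(x_hat.size, -np.inf)
    lb[-1] = 0.0  # sigma2 >= 0

    def f(x):
        p = _params_from_report(x, ps, ph)
        if p is None:
            return np.inf
        val = -data.loglik(p)
        return val if np.isfinite(val) else 1e10

    steps = 1e-4 * np.maximum(np.abs(x_hat), 0.1)
    H = numerical_hessian(f, x_hat, steps=steps, lower_bounds=lb)
    if richardson:
        H2 = numerical_hessian(f, x_hat, steps=steps / 2.0, lower_bounds=lb)
        H = (4.0 * H2 - H) / 3.0

    names = tuple(spec.parameter_names())
    reliable = True
    try:
        eigmin = float(np.linalg.eigvalsh(H).min())
        cond = float(np.linalg.cond(H))
        if eigmin <= 0 or cond > 1e12:
            reliable = False
        cov = np.linalg.pinv(H) if not reliable else np.linalg.inv(H)
    except np.linalg.LinAlgError:
        reliable = False
        cov = np.linalg.pinv(H)
    kappa = math.sqrt(max(data.n * cov[-1, -1], 0.0))
    return InformationMatrix(covariance=cov, kappa=kappa, k=len(names),
                             names=names, n=data.n, reliable=reliable)


_Z = stats.norm.ppf


def wald_ci(fit: FitResult, info: InformationMatrix,
            level: float = 0.95) -> list:
    """SE-based intervals for every parameter except the frailty variance.

    a and b: symmetric interval for ln a / ln b, exponentiated (asymmetric on
    the natural scale).  Regression coefficients: natural scale.
    """
    z = float(_Z(0.5 + level / 2.0))
    p = fit.params
    est_log = {"a": math.log(p.a), "b": math.log(p.b)}
    out = []
    for name in info.names[:-1]:
        se = info.se(name)
        if name in est_log:
            lo, hi = est_log[name] - z * se, est_log[name] + z * se
            out.append(ConfidenceInterval(name, math.exp(lo), math.exp(hi),
                                          level, "wald", info.reliable))
        else:
            est = fit.named_estimates()[name]
            out.append(ConfidenceInterval(name, est - z * se, est + z * se,
                                          level, "wald", info.reliable))
    return out


def mixture_cdf(x, nu: float, kappa: float):
    """CDF of  Phi(nu/k)*TruncNormal(nu, k^2, 0, inf) + Phi(-nu/k)*delta_0.

    With the plug-in weights this simplifies, for x >= 0, to the normal CDF
    Phi((x - nu)/kappa); below 0 the CDF is 0.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, 0.0, stats.norm.cdf((x - nu) / kappa))
    return float(out) if out.ndim == 0 else out


def mixture_quantile(p, nu: float, kappa: float):
    """Quantile function of the truncated-normal + point-mass mixture.

    Quantiles at probability levels inside the zero atom (p <= Phi(-nu/kappa))
    are exactly 0; above the atom the quantile is nu + kappa*z_p.
    """
    p = np.asarray(p, dtype=float)
    q = nu + kappa * stats.norm.ppf(p)
    out = np.maximum(q, 0.0)
    return float(out) if out.ndim == 0 else out


def sigma2_boundary_ci(fit: FitResult, info: InformationMatrix,
                       level: float = 0.95, N: Optional[int] = None) -> ConfidenceInterval:
    """Boundary-aware interval for the frailty variance.

    The asymptotic law of sqrt(N)*sigma2_hat is the mixture
    Phi(nu/kappa)*TN(nu, kappa^2, 0, inf) + Phi(-nu/kappa)*delta_0 with
    plug-in center nu = sqrt(N)*sigma2_hat; its quantiles are mapped back to
    the sigma2 scale.  When sigma2_hat = 0 the lower endpoint is exactly 0.
    """
    N = N or fit.n
    root_n = math.sqrt(N)
    nu = root_n * fit.params.sigma2
    kappa = info.kappa
    alpha = 1.0 - level
    lo = mixture_quantile(alpha / 2.0, nu, kappa) / root_n
    hi = mixture_quantile(1.0 - alpha / 2.0, nu, kappa) / root_n
    if fit.params.sigma2 == 0.0:
        lo = 0.0
    return ConfidenceInterval("sigma2", lo, hi, level, "boundary_mixture",
                              info.reliable)


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

def _profile_index(spec: ModelSpec, target: str) -> int:
    names = spec.parameter_names()
    if target not in names:
        raise KeyError(f"unknown parameter {target!r}; have {names}")
    return names.index(target)


def profile_ci(dataset: SurvivalDataset, spec: ModelSpec, fit: FitResult,
               target_parameter: str, level: float = 0.95,
               options: Optional[FitOptions] = None,
               endpoint_tol: float = 1e-3) -> ConfidenceInterval:
    """Profile-likelihood interval by likelihood-ratio inversion.

    Endpoints v solve 2*(l_max - l_profile(v)) = chi2_{level}(1), found by
    bracketed root finding that expands outward from a Wald-type first guess;
    the inner re-maximizations are warm-started from the neighbouring
    solution.  For sigma2 the profile is evaluated on sigma2 >= 0 only, and
    the lower endpoint is 0 whenever the threshold is not crossed above 0.
    An endpoint whose bracket cannot be expanded to cross the threshold is
    reported as unbounded (+/-inf) with ``reliable=False``.
    """
    options = options or FitOptions(multistart=1, gradient_tolerance=1e-8)
    data = LoglikData(dataset, spec)
    ps, ph = len(spec.scale_covariates), len(spec.shape_covariates)
    idx = _profile_index(spec, target_parameter)
    is_sigma2 = target_parameter == "sigma2"
    is_log_scale = target_parameter in ("a", "b") or is_sigma2
    q = float(stats.chi2.ppf(level, 1))
    l_max = fit.loglik
    x_hat = _pack(fit.params if fit.params.sigma2 > 0 else
                  fit.params.replace(sigma2=1e-8), with_frailty=True)
    # estimation-scale value of the target at the MLE
    v_hat = x_hat[idx]
    warm = {"x": x_hat.copy()}

    def profile_loglik(v_est: float) -> float:
        """l_profile at estimation-scale target value (ln for a/b/sigma2)."""
        x0 = warm["x"].copy()
        x0[idx] = v_est
        x, ll, *_ = _maximize(data, x0, ps, ph, with_frailty=True,
                              options=options, fixed={idx: v_est})
        warm["x"] = x
        return ll

    def l_profile_sigma2_zero() -> float:
        x0 = np.delete(warm["x"].copy(), len(x_hat) - 1)
        _, ll, *_ = _maximize(data, x0, ps, ph, with_frailty=False,
                              options=options)
        return ll

    def deficit(v_est: float) -> float:
        return 2.0 * (l_max - profile_loglik(v_est)) - q

    # initial step on the estimation scale from the observed curvature
    def _initial_step() -> float:
        h = 1e-3 * max(abs(v_hat), 0.1)
        # local quadratic 2(l_max - l_prof) ~ c (v - v_hat)^2
        c = max((deficit(v_hat + h) + deficit(v_hat - h) + 2.0 * q)
                / (2.0 * h ** 2), 1e-8)
        return math.sqrt(q / c)

    step0 = _initial_step()

    def find_endpoint(direction: int):
        """direction=+1 upper, -1 lower; returns (endpoint_est, ok)."""
        lo_v, lo_g = v_hat, -q  # deficit at the MLE
        step = step0
        for _ in range(60):
            v = v_hat + direction * step
            if is_sigma2 and direction < 0 and v < math.log(1e-10):
                # profile hits the sigma2 = 0 boundary
                ll0 = l_profile_sigma2_zero()
                if 2.0 * (l_max - ll0) <= q:
                    return None, True  # boundary inside the interval
                v = math.log(1e-10)
                g = 2.0 * (l_max - ll0) - q
                hi_v, hi_g = v, g
                break
            g = deficit(v)
            if g >= 0:
                hi_v, hi_g = v, g
                break
            lo_v, lo_g = v, g
            step *= 2.0
        else:
            return direction * math.inf, False
        # bracketed root refinement on the estimation scale
        for _ in range(80):
            mid = 0.5 * (lo_v + hi_v)
            g = deficit(mid)
            if abs(g) < endpoint_tol:
                return mid, True
            if g < 0:
                lo_v = mid
            else:
                hi_v = mid
            if abs(hi_v - lo_v) < 1e-12:
                break
        return 0.5 * (lo_v + hi_v), abs(deficit(0.5 * (lo_v + hi_v))) < 10 * endpoint_tol

    up_v, up_ok = find_endpoint(+1)
    lo_v, lo_ok = find_endpoint(-1)

    def back(v):
        if v is None:
            return 0.0
        if math.isinf(v):
            return v
        return math.exp(v) if is_log_scale else v

    lower, upper = back(lo_v), back(up_v)
    if is_sigma2 and lo_v is None:
        lower = 0.0
    if math.isinf(upper) and upper < 0:  # direction sign bookkeeping
        lower, upper = upper, lower
    return ConfidenceInterval(target_parameter, min(lower, upper),
                              max(lower, upper), level, "profile",
                              reliable=up_ok and lo_ok)


def coverage_probability(intervals, truth: float) -> CoverageEstimate:
    """Fraction of replications whose interval contains the truth."""
    hits = [1 if ci.contains(truth) else 0 for ci in intervals]
    n = len(hits)
    if n == 0:
        raise ValueError("need at least one replication")
    p = float(np.mean(hits))
    return CoverageEstimate(value=p, se=math.sqrt(p * (1.0 - p) / n), n=n)
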