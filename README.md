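# doublecox

Parametric survival regression for clustered right-censored data when the
proportional-hazards assumption fails in a structured way: covariates may act
not only on the *level* of the hazard but also on its *shape*.

`doublecox` implements the double-Cox shared-frailty model.  Conditional on a
gamma frailty `Z` (mean 1, variance σ², one draw per cluster), the cumulative
hazard is `Z·H(t|u)` with

* **Weibull**:  `H(t|u) = exp(βs·u) · t^B / a`
* **Gompertz**: `H(t|u) = a·exp(βs·u) · (e^{Bt} − 1) / B`,   `B = b·exp(βh·u)`

so there are two Cox-regression terms: `βs` is the familiar
proportional-hazards effect, and `βh` rescales the shape parameter `b`,
letting hazards fan out or cross between strata — the situation a Gompertz
model meets when, say, birth cohorts age at different rates, or a Weibull
model when device strata wear out with different steepness.  Setting
`βh = 0` recovers the ordinary parametric frailty model.

The gamma frailty integrates out in closed form
(`S(t|u) = (1 + σ²H)^{−1/σ²}`), and the package provides:

* exact marginal likelihood and its analytic score; direct quasi-Newton
  maximum-likelihood fitting plus a gamma-frailty EM cross-check;
* boundary-aware inference for σ² (mixture of a truncated normal and a point
  mass at zero), Wald intervals, and profile-likelihood intervals by
  likelihood-ratio inversion (`2Δl = 3.84` at 95%);
* a reproducible simulation engine (inverse-hazard sampling, shared frailty,
  uniform censoring with a Monte-Carlo-calibrated bound) and a bias/coverage
  study harness;
* CSV in, JSON/TSV reports out, and a small CLI (`doublecox fit / simulate /
  study / lifeexp`).

## Worked example

```python
import numpy as np
from doublecox import (DoubleCoxParams, FitOptions, SimulationConfig,
                       draw_dataset, fit_ml, observed_information,
                       profile_ci, life_expectancy)

truth = DoubleCoxParams(a=20.0, b=1.5, beta_scale=[0.5, 1.0],
                        beta_shape=[0.05, 0.1], sigma2=1.0)
cfg = SimulationConfig(family="weibull", truth=truth, N=2000, Ncl=100,
                       p_cens=0.0, p_Success=0.25, seed=7)
ds = draw_dataset(cfg)
fit = fit_ml(ds, cfg.model_spec(), FitOptions(seed=1))
print({k: round(v, 3) for k, v in fit.named_estimates().items()})
ci = profile_ci(ds, cfg.model_spec(), fit, "beta_scale_Success")
print(f"95% profile CI for the Success scale effect: "
      f"[{ci.lower:.3f}, {ci.upper:.3f}]")
```

prints

```
{'a': 23.999, 'b': 1.513, 'beta_scale_Success': 0.523, 'beta_scale_Score': 0.995,
 'beta_shape_Success': 0.033, 'beta_shape_Score': 0.126, 'sigma2': 1.024}
95% profile CI for the Success scale effect: [0.291, 0.753]
```

All seven parameters are recovered near their true values from a single
replication of 2000 subjects in 100 clusters, and the profile interval for
the binary covariate's scale effect comfortably contains the truth 0.5.
The baseline truths are calibrated to realistic lifetimes — at σ² = 1 the
marginal mean survival is

```python
life_expectancy("gompertz", DoubleCoxParams(a=1e-4, b=0.1, sigma2=1.0)).value
# 69.147  (human longevity)
life_expectancy("weibull", DoubleCoxParams(a=20.0, b=1.5, sigma2=1.0)).value
# 17.819  (hip-prosthesis lifetime)
```

The `examples/` directory contains one short narrative script per
capability: fitting, interval methods, the simulation engine, a small bias
study, and the EM cross-check.

## Documentation

`docs/methods.md` describes the model, the estimation and interval methods,
the simulation design and its calibration, the numerical choices, and the
known limitations (notably the downward bias of σ̂² with few clusters).
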