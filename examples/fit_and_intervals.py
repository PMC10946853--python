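"""Fit a double-Cox frailty model and compare the three interval methods.

Simulates a Weibull dataset with non-proportional hazards (shape effects one
order smaller than scale effects, the benchmark convention), fits by marginal
ML, and prints Wald, boundary-mixture and profile intervals side by side.
"""

from doublecox import (DoubleCoxParams, FitOptions, SimulationConfig,
                       draw_dataset, fit_ml, observed_information, profile_ci,
                       sigma2_boundary_ci, wald_ci)

truth = DoubleCoxParams(a=20.0, b=1.5, beta_scale=[0.5, 1.0],
                        beta_shape=[0.05, 0.1], sigma2=1.0)
cfg = SimulationConfig(family="weibull", truth=truth, N=2000, Ncl=100,
                       p_cens=0.0, p_Success=0.25, seed=7)
ds = draw_dataset(cfg)
spec = cfg.model_spec()

fit = fit_ml(ds, spec, FitOptions(seed=1))
print(f"converged: {fit.converged}   log-likelihood: {fit.loglik:.2f}")
print(f"sigma2 on boundary: {fit.sigma2_boundary}")
print()

info = observed_information(ds, spec, fit.params)
wald = {ci.parameter: ci for ci in wald_ci(fit, info)}
wald["sigma2"] = sigma2_boundary_ci(fit, info)

print(f"{'parameter':22s} {'estimate':>9s} {'truth':>6s}  "
      f"{'wald/mixture':>18s} {'profile':>18s}")
truths = dict(zip(spec.parameter_names(),
                  [truth.a, truth.b, *truth.beta_scale, *truth.beta_shape,
                   truth.sigma2]))
for name, est in fit.named_estimates().items():
    w = wald[name]
    p = profile_ci(ds, spec, fit, name)
    print(f"{name:22s} {est:9.3f} {truths[name]:6.2f}  "
          f"[{w.lower:7.3f},{w.upper:7.3f}] [{p.lower:7.3f},{p.upper:7.3f}]")

print()
print("Wald and profile intervals nearly coincide here (N = 2000 is close to")
print("the quadratic-likelihood regime); the sigma2 interval is the")
print("boundary-aware mixture, whose lower endpoint would clip at 0 if the")
print("variance estimate were within ~2 SEs of the boundary.")
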