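"""Cross-check the direct marginal-ML fit with the gamma-frailty EM.

The two routes maximize the same marginal likelihood by different algorithms,
so their agreement (and the monotone EM likelihood trace) is a strong
internal consistency check of the likelihood code.
"""

import numpy as np

from doublecox import (DoubleCoxParams, FitOptions, SimulationConfig,
                       draw_dataset, fit_em, fit_ml)

truth = DoubleCoxParams(a=1e-4, b=0.1, beta_scale=[0.5, 1.0],
                        beta_shape=[0.05, 0.1], sigma2=1.0)
cfg = SimulationConfig(family="gompertz", truth=truth, N=1000, Ncl=100,
                       p_cens=0.0, p_Success=0.25, seed=5)
ds = draw_dataset(cfg)
spec = cfg.model_spec()

ml = fit_ml(ds, spec, FitOptions(seed=0))
em = fit_em(ds, spec, FitOptions(max_iterations=300), track_loglik=True)

print(f"direct ML : loglik = {ml.loglik:.6f}  ({ml.n_iter} iterations)")
print(f"EM        : loglik = {em.loglik:.6f}  ({em.n_iter} sweeps)")
print(f"loglik gap: {abs(ml.loglik - em.loglik):.2e}")
gap = max(abs(a - b) for a, b in zip(ml.named_estimates().values(),
                                     em.named_estimates().values()))
print(f"largest parameter gap: {gap:.2e}")

trace = em.loglik_trace
print(f"EM trace monotone non-decreasing: {bool(np.all(np.diff(trace) >= -1e-7))}")
print(f"first sweeps: {np.round(trace[:4], 2)} ... -> {trace[-1]:.2f}")
print()
print("EM needs hundreds of sweeps where quasi-Newton needs dozens of")
print("iterations; the direct route is the default for exactly this reason.")
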