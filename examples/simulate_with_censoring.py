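"""Generate clustered survival data with a calibrated censoring rate.

Censoring times are Uniform(0, theta); theta is found by Monte Carlo so that
the *population* probability of censoring equals the requested rate.  The
printout shows the calibrated bound and the realized censoring fraction.
"""

import numpy as np

from doublecox import (DoubleCoxParams, SimulationConfig, calibrate_theta,
                       draw_dataset)

truth = DoubleCoxParams(a=1e-4, b=0.1, beta_scale=[0.5, 1.0],
                        beta_shape=[0.05, 0.1], sigma2=1.0)

for p_cens in (0.4, 0.8):
    cfg = SimulationConfig(family="gompertz", truth=truth, N=50_000, Ncl=100,
                           p_cens=p_cens, p_Success=0.25, seed=11)
    theta = calibrate_theta(cfg)
    ds = draw_dataset(cfg, theta=theta)
    realized = 1.0 - ds.event.mean()
    print(f"target censoring {p_cens:.0%}: theta = {theta:7.2f} years, "
          f"realized {realized:.3f} over N={len(ds)}")

print()
print("A higher target rate needs a smaller uniform bound (censoring times")
print("arrive earlier).  The realized fractions match the targets to within")
print("Monte-Carlo error, which is the end-to-end check of the calibration.")
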