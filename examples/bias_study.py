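"""A small bias study: frailty-variance shrinkage with few clusters.

Runs the study harness on two grid cells that differ only in the number of
clusters and prints the bias of the variance estimate: the downward bias of
sigma2_hat is a known property of marginal ML and fades as clusters multiply.
"""

from doublecox import (DoubleCoxParams, SimulationConfig, StudyConfig,
                       run_bias_study, summarize_to_table)

truth = DoubleCoxParams(a=20.0, b=1.5, beta_scale=[0.5, 1.0],
                        beta_shape=[0.05, 0.1], sigma2=2.0)
grid = [
    SimulationConfig(family="weibull", truth=truth, N=1000, Ncl=10,
                     p_cens=0.0, p_Success=0.25, seed=0),
    SimulationConfig(family="weibull", truth=truth, N=1000, Ncl=100,
                     p_cens=0.0, p_Success=0.25, seed=0),
]
result = run_bias_study(StudyConfig(grid=grid, replications=100, seed=5))

for idx, ncl in ((0, 10), (1, 100)):
    cell = result.cell(idx, "sigma2")
    print(f"Ncl = {ncl:3d}: mean sigma2_hat = {cell['mean_estimate']:.3f} "
          f"(truth 2), bias = {cell['bias']:+.3f} "
          f"+/- {cell['mc_se']:.3f} (MC-SE)")

print()
print("The variance component is underestimated, more so with 10 clusters")
print("than with 100 — the effective sample size for sigma2 is the number of")
print("independent frailty draws, i.e. the number of clusters.  (At 100")
print("replications per cell the effect sits near the Monte-Carlo noise")
print("floor; crank up replications to resolve it sharply.)")
print()
print(summarize_to_table(result, "tsv").splitlines()[0])
print("... full long-format table available via summarize_to_table().")
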