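"""Mean survival times of the benchmark baselines, and a divergent case.

The Gompertz truth (a=1e-4, b=0.1) is calibrated to human longevity and the
Weibull truth (a=20, b=1.5) to the lifetime of a hip prosthesis; both have
frailty variance 1.
"""

from doublecox import DoubleCoxParams, life_expectancy

for family, params, label in [
    ("gompertz", DoubleCoxParams(a=1e-4, b=0.1, sigma2=1.0), "human longevity"),
    ("weibull", DoubleCoxParams(a=20.0, b=1.5, sigma2=1.0), "hip prosthesis"),
    ("weibull", DoubleCoxParams(a=20.0, b=1.5, sigma2=0.0), "no frailty"),
]:
    le = life_expectancy(family, params)
    print(f"{family:9s} a={params.a:<8g} b={params.b:<4g} sigma2={params.sigma2:g}"
          f"  ->  {le.value:7.3f}  ({label})")

# Gamma frailty fattens the survival tail into a power law t^(-B/sigma2);
# when the effective Weibull shape does not exceed the frailty variance the
# mean no longer exists, and the package says so instead of printing a number.
le = life_expectancy("weibull", DoubleCoxParams(a=20.0, b=1.0, sigma2=1.0))
print(f"weibull   a=20       b=1    sigma2=1  ->  finite={le.finite} "
      "(tail ~ 1/t is not integrable)")
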