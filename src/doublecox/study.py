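"""Simulation experiments: bias and interval-coverage tables over a grid.

Each cell of the grid is one `SimulationConfig`; a study runs R independent
replications of generate -> fit (-> intervals), averages the estimates, and
reports bias (mean minus truth), empirical SD, Monte-Carlo SE and per-method
coverage with its binomial SE.  Replications are seeded from the master seed
by (configuration index, replication index), so results are bit-reproducible
regardless of execution order or worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .estimation import FitOptions, fit_ml
from .model import DoubleCoxParams
from .simulate import SimulationConfig, calibrate_theta, draw_dataset
from .uncertainty import (coverage_probability, observed_information,
                          profile_ci, sigma2_boundary_ci, wald_ci)

__all__ = ["StudyConfig", "StudyResult", "run_bias_study",
           "run_coverage_study", "summarize_to_table", "replication_seed"]


@dataclass
class StudyConfig:
    """Grid of scenarios plus replication and interval-method settings."""

    grid: list
    replications: int = 300
    ci_methods: tuple = ()
    level: float = 0.95
    seed: int = 0
    parallel_workers: int = 1
    fit_options: FitOptions = field(default_factory=lambda: FitOptions(multistart=1))

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        bad = set(self.ci_methods) - {"wald", "boundary_mixture", "profile"}
        if bad:
            raise ValueError(f"unknown ci methods: {sorted(bad)}")


@dataclass
class StudyResult:
    """Long-format per-(configuration, parameter) summary."""

    table: pd.DataFrame
    n_replications: int

    def cell(self, config_index: int, parameter: str) -> pd.Series:
        t = self.table
        rows = t[(t.config == config_index) & (t.parameter == parameter)]
        return rows.set_index("metric")["value"]


def replication_seed(master_seed: int, config_index: int, rep: int):
    """Independent, reproducible substream for one replication."""
    return np.random.SeedSequence([master_seed, config_index, rep])


def _truth_values(cfg: SimulationConfig) -> dict:
    p = cfg.truth
    names = cfg.model_spec().parameter_names()
    vals = [p.a, p.b, *p.beta_scale, *p.beta_shape, p.sigma2]
    return dict(zip(names, vals))


def _run_one(cfg, config_index, rep, master_seed, fit_options, theta,
             ci_methods, level, interval_override):
    seed = replication_seed(master_seed, config_index, rep)
    rng = np.random.default_rng(seed)
    ds = draw_dataset(cfg, seed=rng, theta=theta)
    spec = cfg.model_spec()
    try:
        fit = fit_ml(ds, spec, fit_options)
    except Exception:
        return None
    if not fit.converged:
        return None
    est = fit.named_estimates()
    intervals = {}
    if ci_methods:
        if interval_override is not None:
            for m in ci_methods:
                intervals[m] = {n: interval_override(n) for n in est}
        else:
            info = None
            if "wald" in ci_methods or "boundary_mixture" in ci_methods:
                info = observed_information(ds, spec, fit.params)
            if "wald" in ci_methods:
                cis = {ci.parameter: ci for ci in wald_ci(fit, info, level)}
                cis["sigma2"] = sigma2_boundary_ci(fit, info, level)
                intervals["wald"] = cis
            if "boundary_mixture" in ci_methods:
                intervals["boundary_mixture"] = {
                    "sigma2": sigma2_boundary_ci(fit, info, level)}
            if "profile" in ci_methods:
                intervals["profile"] = {
                    n: profile_ci(ds, spec, fit, n, level) for n in est}
    return est, intervals


def _run_study(study: StudyConfig, with_intervals: bool,
               interval_override: Optional[Callable] = None) -> StudyResult:
    rows = []
    ci_methods = tuple(study.ci_methods) if with_intervals else ()
    for ci_idx, cfg in enumerate(study.grid):
        theta = calibrate_theta(cfg) if cfg.p_cens > 0 else None
        tasks = range(study.replications)
        runner = (lambda r: _run_one(cfg, ci_idx, r, study.seed,
                                     study.fit_options, theta, ci_methods,
                                     study.level, interval_override))
        if study.parallel_workers > 1:
            from joblib import Parallel, delayed
            results = Parallel(n_jobs=study.parallel_workers)(
                delayed(runner)(r) for r in tasks)
        else:
            results = [runner(r) for r in tasks]
        # merge deterministically by replication index (results is ordered)
        ok = [r for r in results if r is not None]
        n_fail = len(results) - len(ok)
        truth = _truth_values(cfg)
        flagged = n_fail > 0.2 * study.replications
        est_df = pd.DataFrame([e for e, _ in ok])
        for name in truth:
            col = est_df[name].to_numpy()
            mean, sd = float(col.mean()), float(col.std(ddof=1)) if len(col) > 1 else 0.0
            mc_se = sd / math.sqrt(len(col)) if len(col) else math.nan
            metrics = {
                "mean_estimate": mean,
                "truth": truth[name],
                "bias": mean - truth[name],
                "empirical_sd": sd,
                "mc_se": mc_se,
                "n_converged": float(len(ok)),
                "n_failed": float(n_fail),
            }
            for method in ci_methods:
                per_rep = [iv[method][name] for _, iv in ok
                           if name in iv.get(method, {})]
                if per_rep:
                    cov = coverage_probability(per_rep, truth[name])
                    metrics[f"coverage_{method}"] = cov.value
                    metrics[f"coverage_{method}_se"] = cov.se
            for metric, value in metrics.items():
                rows.append(dict(config=ci_idx, family=cfg.family.value,
                                 N=cfg.N, Ncl=cfg.Ncl, p_cens=cfg.p_cens,
                                 p_Success=cfg.p_Success, parameter=name,
                                 metric=metric, value=value, flagged=flagged))
    return StudyResult(table=pd.DataFrame(rows),
                       n_replications=study.replications)


def run_bias_study(study: StudyConfig) -> StudyResult:
    """Estimate-recovery study: fits only, no intervals."""
    return _run_study(study, with_intervals=False)


def run_coverage_study(study: StudyConfig,
                       interval_override: Optional[Callable] = None) -> StudyResult:
    """Bias plus interval coverage for the requested methods.

    ``interval_override`` (testing hook) maps a parameter name to a
    ConfidenceInterval used in place of the computed ones.
    """
    if not study.ci_methods:
        raise ValueError("run_coverage_study needs at least one ci method")
    return _run_study(study, with_intervals=True,
                      interval_override=interval_override)


def summarize_to_table(result: StudyResult, format: str = "tsv",
                       path=None) -> str:
    """Long-format report (config columns + parameter + metric + value)."""
    if format == "tsv":
        text = result.table.to_csv(sep="\t", index=False)
    elif format == "json":
        text = result.table.to_json(orient="records", indent=2)
    else:
        raise ValueError("format must be 'tsv' or 'json'")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
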