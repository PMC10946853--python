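"""CSV ingestion and fit-report serialization.

The file convention for the status column is configurable through
`ColumnMapping` because both conventions (1 = event and 1 = censored) occur
in the wild; internally event = 1 always means the event was observed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .estimation import FitResult
from .model import SurvivalDataset

__all__ = ["ColumnMapping", "read_survival_csv", "write_fit_report"]


@dataclass(frozen=True)
class ColumnMapping:
    """Names of the required columns and the file's event convention.

    ``status_event_value`` is the raw value in the status column that means
    "event observed" (default 1); every other value in a binary status column
    is read as censored.
    """

    time_column: str = "time"
    status_column: str = "status"
    status_event_value: object = 1
    cluster_column: str = "cluster"
    covariate_columns: tuple = ()


def read_survival_csv(path, mapping: ColumnMapping = ColumnMapping()) -> SurvivalDataset:
    """Read comma-delimited survival data with a header row.

    Validation is strict: times must be positive, the status column must be
    binary after mapping, and missing values anywhere are an error (reported
    with 1-based data row numbers).
    """
    df = pd.read_csv(path)
    needed = [mapping.time_column, mapping.status_column, mapping.cluster_column,
              *mapping.covariate_columns]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")

    na_rows = df[needed].isna().any(axis=1)
    if na_rows.any():
        raise ValueError(
            f"missing values in data rows {[int(i) + 1 for i in np.where(na_rows)[0]]}")

    time = df[mapping.time_column].to_numpy(dtype=float)
    bad = np.where(~(time > 0))[0]
    if bad.size:
        raise ValueError(
            f"non-positive time in data rows {[int(i) + 1 for i in bad]}")

    raw_status = df[mapping.status_column]
    distinct = set(raw_status.unique().tolist())
    if len(distinct) > 2:
        raise ValueError(f"status column has more than two values: {sorted(map(str, distinct))}")
    if mapping.status_event_value not in distinct and len(distinct) == 2:
        raise ValueError(
            f"status_event_value {mapping.status_event_value!r} does not occur "
            f"in the status column (values: {sorted(map(str, distinct))})")
    event = (raw_status == mapping.status_event_value).astype(int).to_numpy()

    covs = df[list(mapping.covariate_columns)] if mapping.covariate_columns else None
    return SurvivalDataset(time, event, df[mapping.cluster_column].to_numpy(), covs)


def write_fit_report(fit: FitResult, intervals=None, path=None,
                     format: str = "json", seed: Optional[int] = None):
    """Serialize a fit (and optional intervals) to JSON or TSV.

    The report always contains a sigma2 row, flagged when the estimate sits
    on the boundary.  Returns the report text; writes it when ``path`` given.
    """
    intervals = intervals or []
    by_param = {}
    for ci in intervals:
        by_param.setdefault(ci.parameter, []).append(ci)

    est = fit.named_estimates()
    rows = []
    for name, value in est.items():
        row = dict(parameter=name, estimate=value)
        if name == "sigma2":
            row["boundary"] = fit.sigma2_boundary
        for ci in by_param.get(name, []):
            row.setdefault("intervals", []).append(dict(
                lower=ci.lower, upper=ci.upper, level=ci.level,
                method=ci.method, reliable=ci.reliable))
        rows.append(row)

    report = dict(
        model=dict(family=fit.spec.family.value,
                   scale_covariates=list(fit.spec.scale_covariates),
                   shape_covariates=list(fit.spec.shape_covariates)),
        estimates=rows,
        loglik=fit.loglik,
        converged=fit.converged,
        n_iterations=fit.n_iter,
        gradient_norm=None if not np.isfinite(fit.gradient_norm) else fit.gradient_norm,
        method=fit.method,
        n=fit.n, n_clusters=fit.n_clusters,
        sigma2_boundary=fit.sigma2_boundary,
        software_version=__version__,
        seed=seed,
    )

    if format == "json":
        text = json.dumps(report, indent=2)
    elif format == "tsv":
        flat = []
        for row in rows:
            base = dict(parameter=row["parameter"], estimate=row["estimate"])
            if row.get("intervals"):
                for ci in row["intervals"]:
                    flat.append({**base, **ci})
            else:
                flat.append(base)
        text = pd.DataFrame(flat).to_csv(sep="\t", index=False)
    else:
        raise ValueError("format must be 'json' or 'tsv'")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def report_to_estimates(text: str) -> dict:
    """Parse a JSON fit report back into {parameter: estimate}."""
    report = json.loads(text)
    return {row["parameter"]: row["estimate"] for row in report["estimates"]}
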