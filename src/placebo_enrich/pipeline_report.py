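"""Orchestrate the analysis suite and emit descriptive/regression reports.

The suite mirrors a full study-level enrichment analysis:

* a descriptive table of placebo-group characteristics per severity group
  (unweighted mean, SD, min/max, median, quartiles, IQR),
* the primary model: abstinence rate ~ treatment duration + dichotomous
  population severity, on the studies that survive allocation,
* sensitivity models replacing the dichotomous factor with the continuous
  "% high-severity patients" statistic (normal or lognormal moments), with
  an "extended" variant re-admitting exclusion-zone studies,
* secondary models adjusting for other baseline characteristics, subject to
  a minimum-coverage rule (a covariate must be reported in at least 10
  studies), and
* a prediction grid (population x month) with confidence intervals plus the
  per-group regression-line data needed for plotting.

All computation is on the proportion scale; percent formatting belongs to
the reporting boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .meta_regression import (
    MetaDataset,
    MetaRegressionResult,
    Prediction,
    fit_meta_regression,
    predict,
    within_study_variance,
)
from .severity_allocation import SeverityAllocation, ThresholdPolicy, allocate
from .severity_fraction import Distribution, fractions_for_study
from .study_data import StudyRecord, abstinence_rate

logger = logging.getLogger(__name__)

MIN_COVERAGE_STUDIES = 10

#: The four printed secondary covariate configurations.
SECONDARY_SETS: dict[str, tuple[str, ...]] = {
    "age_male": ("duration", "severity", "mean_age", "pct_male"),
    "consumption": ("duration", "consumption"),
    "abs_duration": ("duration", "abs_duration"),
    "abs_duration_consumption": ("duration", "abs_duration", "consumption"),
}


class CoverageError(ValueError):
    """A covariate is reported in fewer studies than the coverage rule allows."""


@dataclass
class ModelFit:
    """One fitted model plus the bookkeeping of which studies entered it."""

    name: str
    result: MetaRegressionResult
    data: MetaDataset
    included_ids: list[str]
    excluded_ids: list[str] = field(default_factory=list)


@dataclass
class AnalysisSuiteResult:
    """Descriptive table, fitted models, and the prediction grid."""

    descriptive: pd.DataFrame
    models: list[ModelFit]
    predictions: pd.DataFrame
    excluded_ids: list[str]


def _summary_stats(values: Sequence[float]) -> dict[str, float]:
    """Unweighted summary of one characteristic across studies.

    Quartiles use linear interpolation between order statistics;
    IQR = Q3 - Q1 exactly.
    """
    x = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if x.size == 0:
        return {}
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }


def iqr_from_quartiles(q1: float, q3: float) -> float:
    """Interquartile range from the first and third quartiles."""
    return q3 - q1


_CHARACTERISTICS = [
    ("sample_size", lambda r, f: float(r.n_placebo)),
    ("duration_months", lambda r, f: r.duration_months),
    ("mean_age", lambda r, f: r.mean_age),
    ("pct_male", lambda r, f: None if r.pct_male is None else 100.0 * r.pct_male),
    ("consumption_g_day", lambda r, f: r.consumption_mean),
    ("abstinence_days", lambda r, f: r.abstinence_days_mean),
    ("pct_hvh_drl", lambda r, f: None if f is None else 100.0 * f.frac_hvh),
    ("pct_not_early", lambda r, f: None if f is None else 100.0 * f.frac_not_early),
    ("pct_high_severity", lambda r, f: None if f is None else 100.0 * f.frac_high_severity),
    ("abstinence_rate_pct", lambda r, f: 100.0 * abstinence_rate(r)),
]


def descriptive_table(
    records: Sequence[StudyRecord],
    allocations: Sequence[SeverityAllocation],
    threshold_policy: ThresholdPolicy = "weighted",
) -> pd.DataFrame:
    """Per-group and overall unweighted descriptive statistics.

    Severity fractions (normal assumption) are included among the
    characteristics when the study's moments allow them.  Groups with no
    studies are omitted with a warning.
    """
    groups: dict[str, list[tuple[StudyRecord, object]]] = {"overall": []}
    for rec, alloc in zip(records, allocations):
        try:
            fr = fractions_for_study(rec, "normal", threshold_policy)
        except ValueError:
            fr = None
        groups["overall"].append((rec, fr))
        groups.setdefault(alloc.population, []).append((rec, fr))

    rows = []
    for group in ("overall", "mild", "high", "excluded"):
        members = groups.get(group, [])
        if not members:
            if group in ("mild", "high"):
                logger.warning("descriptive table: group %r is empty and was omitted", group)
            continue
        n_patients = int(sum(r.n_placebo for r, _ in members))
        for char, getter in _CHARACTERISTICS:
            stats = _summary_stats([getter(r, f) for r, f in members])
            if not stats:
                continue
            rows.append(
                {"group": group, "n_studies": len(members), "n_patients": n_patients,
                 "characteristic": char, **stats}
            )
    return pd.DataFrame(rows)


def _covariate_value(
    rec: StudyRecord,
    name: str,
    severity_lookup: Mapping[str, float] | None,
) -> float | None:
    if name == "duration":
        return rec.duration_months
    if name == "severity":
        return None if severity_lookup is None else severity_lookup.get(rec.study_id)
    if name == "mean_age":
        return rec.mean_age
    if name == "pct_male":
        return rec.pct_male
    if name == "consumption":
        return rec.consumption_mean
    if name == "abs_duration":
        return rec.abstinence_days_mean
    raise ValueError(f"unknown covariate {name!r}")


def build_meta_dataset(
    records: Sequence[StudyRecord],
    covariates: Sequence[str],
    severity_lookup: Mapping[str, float] | None = None,
    enforce_coverage: bool = False,
) -> tuple[MetaDataset, list[str]]:
    """Assemble outcome, binomial variances, and design matrix.

    Studies missing any requested covariate are dropped (complete-case);
    the dropped ids are returned.  With ``enforce_coverage`` a covariate
    reported in fewer than 10 studies raises :class:`CoverageError`.
    """
    if enforce_coverage:
        for name in covariates:
            n_reported = sum(
                1 for r in records if _covariate_value(r, name, severity_lookup) is not None
            )
            if n_reported < MIN_COVERAGE_STUDIES:
                raise CoverageError(
                    f"covariate {name!r} is reported in only {n_reported} studies; "
                    f"the coverage rule requires at least {MIN_COVERAGE_STUDIES}"
                )
    ys, vs, rows, ids, dropped = [], [], [], [], []
    for rec in records:
        xs = [1.0]
        complete = True
        for name in covariates:
            val = _covariate_value(rec, name, severity_lookup)
            if val is None:
                complete = False
                break
            xs.append(float(val))
        if not complete:
            dropped.append(rec.study_id)
            continue
        ys.append(abstinence_rate(rec))
        if rec.n_abstinent is not None:
            vs.append(within_study_variance(rec.n_abstinent, rec.n_placebo))
        else:
            # rate-only studies: back out an effective count at the reported rate
            n_eff = int(round(abstinence_rate(rec) * rec.n_placebo))
            vs.append(within_study_variance(n_eff, rec.n_placebo))
        rows.append(xs)
        ids.append(rec.study_id)
    data = MetaDataset(
        y=np.asarray(ys),
        v=np.asarray(vs),
        X=np.asarray(rows),
        study_ids=ids,
        term_names=["intercept"] + list(covariates),
    )
    return data, dropped


def run_primary(
    records: Sequence[StudyRecord],
    threshold_policy: ThresholdPolicy = "weighted",
    **fit_options,
) -> ModelFit:
    """Main model: abstinence rate ~ duration + dichotomous severity.

    Exclusion-zone (indeterminate) studies are dropped and listed in the
    fit's ``excluded_ids``, never silently discarded.
    """
    allocations = [allocate(r, threshold_policy) for r in records]
    severity = {}
    excluded = []
    kept = []
    for rec, alloc in zip(records, allocations):
        if alloc.population == "excluded":
            excluded.append(rec.study_id)
            continue
        severity[rec.study_id] = 1.0 if alloc.population == "high" else 0.0
        kept.append(rec)
    data, dropped = build_meta_dataset(kept, ["duration", "severity"], severity)
    result = fit_meta_regression(data, **fit_options)
    return ModelFit("primary", result, data, list(data.study_ids), excluded + dropped)


def run_sensitivity(
    records: Sequence[StudyRecord],
    distribution: Distribution = "normal",
    extended: bool = False,
    threshold_policy: ThresholdPolicy = "weighted",
    **fit_options,
) -> ModelFit:
    """Sensitivity model with the continuous % high-severity covariate.

    ``extended`` re-admits exclusion-zone studies using their computed
    severity fraction (their moments still identify a % of high-severity
    patients even though the dichotomy cannot).
    """
    allocations = [allocate(r, threshold_policy) for r in records]
    frac = {}
    excluded = []
    kept = []
    for rec, alloc in zip(records, allocations):
        if alloc.population == "excluded" and not extended:
            excluded.append(rec.study_id)
            continue
        frac[rec.study_id] = fractions_for_study(
            rec, distribution, threshold_policy
        ).frac_high_severity
        kept.append(rec)
    name = f"sensitivity_{distribution}" + ("_extended" if extended else "")
    data, dropped = build_meta_dataset(kept, ["duration"], None)
    # pct_high_severity is a derived covariate, not a record field: append it
    X = np.column_stack([data.X, [frac[sid] for sid in data.study_ids]])
    data = MetaDataset(
        X=X, y=data.y, v=data.v, study_ids=data.study_ids,
        term_names=["intercept", "duration", "pct_high_severity"],
    )
    result = fit_meta_regression(data, **fit_options)
    return ModelFit(name, result, data, list(data.study_ids), excluded + dropped)


def run_secondary(
    records: Sequence[StudyRecord],
    covariate_set: str | Sequence[str],
    threshold_policy: ThresholdPolicy = "weighted",
    **fit_options,
) -> ModelFit:
    """Secondary model over one of the named covariate configurations.

    ``covariate_set`` is one of ``age_male``, ``consumption``,
    ``abs_duration``, ``abs_duration_consumption``, or an explicit list of
    covariate names (possibly empty, giving the intercept-only
    heterogeneity fit).  Complete-case per model, with the per-model k in
    the result; a covariate reported in fewer than 10 studies is refused.
    """
    if isinstance(covariate_set, str):
        try:
            covariates = SECONDARY_SETS[covariate_set]
        except KeyError:
            raise ValueError(
                f"unknown covariate set {covariate_set!r}; "
                f"choose from {sorted(SECONDARY_SETS)} or pass an explicit list"
            ) from None
        name = f"secondary_{covariate_set}"
    else:
        covariates = tuple(covariate_set)
        name = "secondary_custom" if covariates else "heterogeneity_only"

    allocations = [allocate(r, threshold_policy) for r in records]
    severity = {}
    excluded = []
    kept = []
    for rec, alloc in zip(records, allocations):
        if alloc.population == "excluded":
            excluded.append(rec.study_id)
            continue
        severity[rec.study_id] = 1.0 if alloc.population == "high" else 0.0
        kept.append(rec)
    data, dropped = build_meta_dataset(kept, covariates, severity, enforce_coverage=True)
    result = fit_meta_regression(data, **fit_options)
    return ModelFit(name, result, data, list(data.study_ids), excluded + dropped)


def prediction_grid(
    fit: ModelFit,
    months: Sequence[float] = (3.0, 6.0),
    populations: Sequence[str] = ("mild", "high"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predicted abstinence rate per (population, month) cell with CIs.

    For the primary model the population maps to the 0/1 severity
    indicator; for sensitivity models it maps to a % of high-severity
    patients of 0% (mild) or 100% (high).  Months outside the fitted
    duration range are flagged as extrapolated.
    """
    terms = list(fit.result.term_names)
    if terms[:2] != ["intercept", "duration"] or len(terms) != 3 or terms[2] not in (
        "severity",
        "pct_high_severity",
    ):
        raise ValueError("prediction grid expects an intercept + duration + severity-type model")
    durations = fit.data.X[:, 1]
    rows = []
    for pop in populations:
        sev = {"mild": 0.0, "high": 1.0}[pop]
        for month in months:
            pred = predict(fit.result, [1.0, month, sev], alpha)
            rows.append(
                {
                    "model": fit.name,
                    "population": pop,
                    "month": month,
                    "predicted": pred.point,
                    "ci_low": pred.ci_low,
                    "ci_high": pred.ci_high,
                    "extrapolated": bool(month < durations.min() or month > durations.max()),
                }
            )
    return pd.DataFrame(rows)


def regression_line_data(
    fit: ModelFit, records: Sequence[StudyRecord] | None = None, n_points: int = 50
) -> pd.DataFrame:
    """Per-group regression line with confidence band, plus study points.

    Returns long-format plot data: line rows carry (population, month,
    predicted, ci_low, ci_high); point rows carry each study's duration,
    observed rate, and arm size (for marker sizing) when ``records`` are
    supplied.
    """
    n_by_id = {r.study_id: r.n_placebo for r in records} if records else {}
    durations = fit.data.X[:, 1]
    grid = np.linspace(durations.min(), durations.max(), n_points)
    rows = []
    for pop, sev in (("mild", 0.0), ("high", 1.0)):
        for month in grid:
            pred = predict(fit.result, [1.0, month, sev], 0.05)
            rows.append(
                {"kind": "line", "population": pop, "month": float(month),
                 "value": pred.point, "ci_low": pred.ci_low, "ci_high": pred.ci_high,
                 "n_placebo": np.nan, "study_id": ""}
            )
    sev_col = fit.data.X[:, 2]
    for sid, month, y, w in zip(fit.data.study_ids, durations, fit.data.y, sev_col):
        rows.append(
            {"kind": "study", "population": "high" if w >= 0.5 else "mild",
             "month": float(month), "value": float(y), "ci_low": np.nan, "ci_high": np.nan,
             "n_placebo": float(n_by_id.get(sid, np.nan)), "study_id": sid}
        )
    return pd.DataFrame(rows)


DEFAULT_SUITES = ("primary", "sensitivity-normal", "sensitivity-lognormal", "extended", "secondary")


def run_suite(
    records: Sequence[StudyRecord],
    suites: Sequence[str] = DEFAULT_SUITES,
    threshold_policy: ThresholdPolicy = "weighted",
    months: Sequence[float] = (3.0, 6.0),
    **fit_options,
) -> AnalysisSuiteResult:
    """Run the requested analyses and assemble the full report."""
    allocations = [allocate(r, threshold_policy) for r in records]
    excluded = [r.study_id for r, a in zip(records, allocations) if a.population == "excluded"]
    descriptive = descriptive_table(records, allocations, threshold_policy)

    models: list[ModelFit] = []
    for suite in suites:
        if suite == "primary":
            models.append(run_primary(records, threshold_policy, **fit_options))
        elif suite == "sensitivity-normal":
            models.append(run_sensitivity(records, "normal", False, threshold_policy, **fit_options))
        elif suite == "sensitivity-lognormal":
            models.append(run_sensitivity(records, "lognormal", False, threshold_policy, **fit_options))
        elif suite == "extended":
            models.append(run_sensitivity(records, "normal", True, threshold_policy, **fit_options))
        elif suite == "secondary":
            for set_name in SECONDARY_SETS:
                try:
                    models.append(run_secondary(records, set_name, threshold_policy, **fit_options))
                except CoverageError as err:
                    logger.warning("secondary model %r skipped: %s", set_name, err)
        else:
            raise ValueError(f"unknown suite {suite!r}")

    grids = [
        prediction_grid(fit, months)
        for fit in models
        if len(fit.result.term_names) == 3
        and fit.result.term_names[1] == "duration"
        and fit.result.term_names[2] in ("severity", "pct_high_severity")
    ]
    predictions = pd.concat(grids, ignore_index=True) if grids else pd.DataFrame()
    return AnalysisSuiteResult(descriptive, models, predictions, excluded)


def models_table(models: Iterable[ModelFit]) -> pd.DataFrame:
    """Long-format coefficient/heterogeneity table across fitted models."""
    rows = []
    for fit in models:
        res = fit.result
        for j, term in enumerate(res.term_names):
            rows.append(
                {
                    "model": fit.name,
                    "term": term,
                    "estimate": res.beta[j],
                    "se": res.se[j],
                    "p_value": res.pval[j],
                    "tau2": res.tau2,
                    "i2": res.i2,
                    "adjusted_r2": res.adjusted_r2,
                    "k": res.k,
                }
            )
    return pd.DataFrame(rows)


def write_report(result: AnalysisSuiteResult, outdir: str | Path, config: Mapping | None = None) -> None:
    """Write table1/table2/table3 CSVs, plot data, and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.descriptive.to_csv(outdir / "table1.csv", index=False)
    models_table(result.models).to_csv(outdir / "table2.csv", index=False)
    result.predictions.to_csv(outdir / "table3.csv", index=False)
    primary = next((m for m in result.models if m.name == "primary"), None)
    if primary is not None:
        regression_line_data(primary).to_csv(outdir / "figure3_data.csv", index=False)
    with open(outdir / "excluded_studies.txt", "w") as fh:
        for sid in result.excluded_ids:
            fh.write(sid + "\n")
    if config is not None:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(dict(config), fh)
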