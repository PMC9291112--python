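"""Decision tree assigning each study to a mild- or high-severity population.

Two study-level criteria drive the allocation:

1.  Drinking risk level (DRL).  A placebo group whose mean baseline alcohol
    consumption is *lower than* the WHO medium-DRL threshold (60 g/day for
    men, 40 g/day for women) is a low/medium-DRL (LM) study; otherwise it is
    a high/very-high-DRL (HVH) study.  LM studies are mild-severity
    regardless of abstinence duration.
2.  Pre-treatment abstinence.  Among HVH studies, those conducted in "not
    early abstainers" (abstinent less than 14 days before treatment start)
    are high-severity; those conducted in early abstainers are
    mild-severity.  The inclusion/exclusion criteria decide when they bound
    the detoxification period across 14 days; otherwise the reported mean
    abstinence duration decides (<=11 days: not early; >=17 days: early;
    strictly between: indeterminate, and the study is excluded because it
    plausibly mixes both kinds of patients).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .study_data import StudyRecord

MALE_THRESHOLD_G = 60.0
FEMALE_THRESHOLD_G = 40.0
EARLY_ABSTAINER_DAYS = 14.0
MEAN_NOT_EARLY_MAX = 11.0
MEAN_EARLY_MIN = 17.0

ThresholdPolicy = Literal["weighted", "male_60", "female_40"]


@dataclass(frozen=True)
class SeverityAllocation:
    """Outcome of the allocation decision tree for one study."""

    drl_class: Literal["LM", "HVH"]
    abstainer_class: Literal["early", "not_early", "indeterminate"]
    population: Literal["mild", "high", "excluded"]
    basis: Literal["criteria", "mean_duration", "not_applicable"]


def drl_threshold(record: StudyRecord, policy: ThresholdPolicy = "weighted") -> float:
    """Study-level medium-DRL threshold in g/day.

    The WHO thresholds are per-sex but trials report a single group mean, so
    the default policy interpolates by the group's sex composition:
    ``pct_male * 60 + (1 - pct_male) * 40``.  The ``male_60`` / ``female_40``
    policies apply a single per-sex threshold to every study.
    """
    if policy == "male_60":
        return MALE_THRESHOLD_G
    if policy == "female_40":
        return FEMALE_THRESHOLD_G
    if policy == "weighted":
        if record.pct_male is None:
            raise ValueError(
                f"study {record.study_id!r}: threshold policy 'weighted' requires pct_male"
            )
        return record.pct_male * MALE_THRESHOLD_G + (1.0 - record.pct_male) * FEMALE_THRESHOLD_G
    raise ValueError(f"unknown threshold policy {policy!r}")


def classify_drl(record: StudyRecord, policy: ThresholdPolicy = "weighted") -> str:
    """Classify a study as LM or HVH DRL by its mean baseline consumption.

    "Lower than" is strict: a mean exactly at the threshold is HVH.
    Requires consumption normalized to g/day.
    """
    if record.consumption_unit != "grams_per_day":
        raise ValueError(
            f"study {record.study_id!r}: consumption must be normalized to g/day first"
        )
    return "LM" if record.consumption_mean < drl_threshold(record, policy) else "HVH"


def classify_abstainer(record: StudyRecord) -> tuple[str, str]:
    """Classify the study population as early / not-early abstainers.

    Returns ``(abstainer_class, basis)``.  The inclusion/exclusion criteria
    rule has precedence; the mean abstinence duration is the fallback.
    """
    if record.detox_max_days is not None and record.detox_max_days <= EARLY_ABSTAINER_DAYS:
        return "not_early", "criteria"
    if record.detox_min_days is not None and record.detox_min_days >= EARLY_ABSTAINER_DAYS:
        return "early", "criteria"
    mean = record.abstinence_days_mean
    if mean is None:
        raise ValueError(
            f"study {record.study_id!r}: neither detoxification criteria nor a mean "
            "abstinence duration is available"
        )
    if mean <= MEAN_NOT_EARLY_MAX:
        return "not_early", "mean_duration"
    if mean >= MEAN_EARLY_MIN:
        return "early", "mean_duration"
    return "indeterminate", "mean_duration"


def allocate(record: StudyRecord, policy: ThresholdPolicy = "weighted") -> SeverityAllocation:
    """Run the full decision tree for one study.

    LM studies short-circuit to the mild-severity population and never reach
    the abstainer rule's exclusion branch.
    """
    drl = classify_drl(record, policy)
    if drl == "LM":
        # abstainer class is still reported when computable, for transparency
        try:
            abst, basis = classify_abstainer(record)
        except ValueError:
            abst, basis = "indeterminate", "not_applicable"
        return SeverityAllocation(drl, abst, "mild", basis)
    abst, basis = classify_abstainer(record)
    if abst == "not_early":
        population = "high"
    elif abst == "early":
        population = "mild"
    else:
        population = "excluded"
    return SeverityAllocation(drl, abst, population, basis)


def allocate_table(
    records: Iterable[StudyRecord], policy: ThresholdPolicy = "weighted"
) -> pd.DataFrame:
    """Allocate every record; returns one row per study with the decision."""
    rows = []
    for rec in records:
        alloc = allocate(rec, policy)
        rows.append(
            {
                "study_id": rec.study_id,
                "drl_class": alloc.drl_class,
                "abstainer_class": alloc.abstainer_class,
                "population": alloc.population,
                "basis": alloc.basis,
            }
        )
    return pd.DataFrame(rows, columns=["study_id", "drl_class", "abstainer_class", "population", "basis"])
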