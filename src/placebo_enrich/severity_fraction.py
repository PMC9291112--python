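"""Continuous "% high-severity patients" statistic from reported moments.

Study allocation by group means ignores that a trial may enroll a mix of
mild- and high-severity patients.  This module estimates, per study, the
share of patients who are high-severity: the product of

* ``frac_hvh`` — the share of patients whose daily consumption is at or
  above the medium-DRL threshold, and
* ``frac_not_early`` — the share abstinent for fewer than 14 days before
  treatment start,

each computed as a tail probability of a distribution matched to the
reported mean and standard deviation.  The two criteria are assumed
independent.  The primary computation assumes normal distributions; a
lognormal alternative (moment-matched, so the arithmetic mean and SD are
preserved) probes sensitivity to the strictly positive, right-skewed nature
of consumption and abstinence data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import stats

from .severity_allocation import EARLY_ABSTAINER_DAYS, ThresholdPolicy, drl_threshold
from .study_data import StudyRecord

Side = Literal["at_or_above", "below"]
Distribution = Literal["normal", "lognormal"]


@dataclass(frozen=True)
class SeverityFractions:
    """Per-study severity fractions and the distribution they assume."""

    frac_hvh: float
    frac_not_early: float
    frac_high_severity: float
    distribution: Distribution


def _degenerate_tail(mean: float, threshold: float, side: Side) -> float:
    # all mass at the mean; ties go to the at_or_above side, mirroring the
    # strict "lower than" DRL rule
    if side == "at_or_above":
        return 1.0 if mean >= threshold else 0.0
    return 1.0 if mean < threshold else 0.0


def tail_fraction_normal(mean: float, sd: float, threshold: float, side: Side) -> float:
    """Gaussian tail probability for the given side of a threshold."""
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if side not in ("at_or_above", "below"):
        raise ValueError(f"unknown side {side!r}")
    if sd == 0:
        return _degenerate_tail(mean, threshold, side)
    if side == "at_or_above":
        return float(stats.norm.sf(threshold, loc=mean, scale=sd))
    return float(stats.norm.cdf(threshold, loc=mean, scale=sd))


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale parameters (mu, sigma) matching an arithmetic mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2),  mu = ln(mean) - sigma^2/2.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive for a lognormal fit, got {mean}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def tail_fraction_lognormal(mean: float, sd: float, threshold: float, side: Side) -> float:
    """Tail probability under a lognormal moment-matched to (mean, sd)."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if side not in ("at_or_above", "below"):
        raise ValueError(f"unknown side {side!r}")
    if sd == 0:
        return _degenerate_tail(mean, threshold, side)
    mu, sigma = lognormal_from_moments(mean, sd)
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    if side == "at_or_above":
        return float(dist.sf(threshold))
    return float(dist.cdf(threshold))


def frac_high_severity(frac_not_early: float, frac_hvh: float) -> float:
    """Share of high-severity patients assuming the two criteria independent.

    E.g. 80% not early abstainers and 70% H/VH-DRL patients give
    0.80 * 0.70 = 0.56, i.e. 56% high-severity patients.
    """
    for name, value in (("frac_not_early", frac_not_early), ("frac_hvh", frac_hvh)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    return frac_not_early * frac_hvh


_TAIL = {"normal": tail_fraction_normal, "lognormal": tail_fraction_lognormal}


def fractions_for_study(
    record: StudyRecord,
    distribution: Distribution = "normal",
    threshold_policy: ThresholdPolicy = "weighted",
) -> SeverityFractions:
    """Compute all three severity fractions for one study.

    ``frac_hvh`` is the at-or-above tail of the consumption distribution at
    the study's DRL threshold; ``frac_not_early`` is the below-14-days tail
    of the abstinence-duration distribution.
    """
    if distribution not in _TAIL:
        raise ValueError(f"unknown distribution {distribution!r}")
    if record.abstinence_days_mean is None:
        raise ValueError(f"study {record.study_id!r}: abstinence_days_mean is missing")
    if record.abstinence_days_sd is None:
        raise ValueError(f"study {record.study_id!r}: abstinence_days_sd is missing")
    tail = _TAIL[distribution]
    threshold = drl_threshold(record, threshold_policy)
    frac_hvh = tail(record.consumption_mean, record.consumption_sd, threshold, "at_or_above")
    if distribution == "lognormal" and record.abstinence_days_mean == 0:
        # zero mean abstinence has no lognormal representation: everyone
        # started treatment immediately, so nobody is an early abstainer
        frac_not_early = 1.0
    else:
        frac_not_early = tail(
            record.abstinence_days_mean,
            record.abstinence_days_sd,
            EARLY_ABSTAINER_DAYS,
            "below",
        )
    return SeverityFractions(
        frac_hvh=frac_hvh,
        frac_not_early=frac_not_early,
        frac_high_severity=frac_high_severity(frac_not_early, frac_hvh),
        distribution=distribution,
    )
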