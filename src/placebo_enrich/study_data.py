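"""Study-level data model for placebo arms of abstinence-endpoint RCTs.

One :class:`StudyRecord` holds the summary data extracted from a single
trial's placebo arm: sample size, number of continuously abstinent patients
(dropouts count as failures), intended treatment duration, baseline alcohol
consumption moments, pre-treatment abstinence-duration moments, and optional
demographics and inclusion-criteria detoxification bounds.

All rates are stored as proportions in [0, 1]; consumption is normalized to
grams of pure alcohol per day using country-specific standard-drink sizes
when a study reports drinks/day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Grams of pure alcohol per standard drink, by country.  User-extensible;
#: seeded with the WHO-derived values for the countries that commonly report
#: drinks/day instead of g/day.
DEFAULT_DRINK_GRAMS: dict[str, float] = {
    "south korea": 8.0,
    "australia": 10.0,
    "belgium": 10.0,
    "france": 10.0,
    "italy": 12.0,
    "united states": 14.0,
    "germany": 15.0,
}

_COUNTRY_ALIASES = {
    "usa": "united states",
    "us": "united states",
    "united states of america": "united states",
}

GRAMS_PER_DAY = "grams_per_day"
DRINKS_PER_DAY = "drinks_per_day"

#: Columns of the canonical extraction-table CSV, in write order.
CSV_COLUMNS = [
    "study_id",
    "n_placebo",
    "n_abstinent",
    "abstinence_rate",
    "duration_months",
    "consumption_mean",
    "consumption_sd",
    "consumption_unit",
    "country",
    "abstinence_days_mean",
    "abstinence_days_sd",
    "detox_max_days",
    "detox_min_days",
    "pct_male",
    "mean_age",
]

_MANDATORY_COLUMNS = [
    "study_id",
    "n_placebo",
    "duration_months",
    "consumption_mean",
    "consumption_sd",
]


class SchemaError(ValueError):
    """The input table is missing a mandatory column or uses a bad layout."""


class RecordValidationError(ValueError):
    """A single study row violates a record invariant; carries the study id."""

    def __init__(self, study_id: str, message: str):
        self.study_id = study_id
        super().__init__(f"study {study_id!r}: {message}")


class DrinkConversionTable:
    """Country -> grams of pure alcohol per standard drink.

    Lookup is case-insensitive and tolerant of the common aliases for the
    United States.  Extra countries may be supplied at construction (e.g.
    from a YAML config ``drink_grams: {country: grams}`` block).
    """

    def __init__(self, extra: Mapping[str, float] | None = None):
        table = dict(DEFAULT_DRINK_GRAMS)
        if extra:
            for country, grams in extra.items():
                grams = float(grams)
                if grams <= 0:
                    raise ValueError(
                        f"grams per drink must be positive, got {grams} for {country!r}"
                    )
                table[self._normalize(country)] = grams
        self._table = table

    @staticmethod
    def _normalize(country: str) -> str:
        key = country.strip().casefold()
        return _COUNTRY_ALIASES.get(key, key)

    def __contains__(self, country: str) -> bool:
        return self._normalize(country) in self._table

    def __getitem__(self, country: str) -> float:
        key = self._normalize(country)
        try:
            return self._table[key]
        except KeyError:
            known = ", ".join(sorted(self._table))
            raise KeyError(
                f"no standard-drink size for country {country!r}; known countries: {known}"
            ) from None

    def countries(self) -> list[str]:
        return sorted(self._table)


@dataclass
class StudyRecord:
    """Summary data for one placebo arm.

    Either ``n_abstinent`` (count of continuously abstinent patients at end
    of treatment) or ``abstinence_rate`` (a proportion) must be present;
    when both are given the count representation is authoritative.
    """

    study_id: str
    n_placebo: int
    duration_months: float
    consumption_mean: float
    consumption_sd: float
    n_abstinent: int | None = None
    abstinence_rate: float | None = None
    consumption_unit: str = GRAMS_PER_DAY
    country: str | None = None
    abstinence_days_mean: float | None = None
    abstinence_days_sd: float | None = None
    detox_max_days: float | None = None
    detox_min_days: float | None = None
    pct_male: float | None = None
    mean_age: float | None = None

    def __post_init__(self) -> None:
        sid = self.study_id
        if self.n_placebo <= 0 or int(self.n_placebo) != self.n_placebo:
            raise RecordValidationError(sid, f"n_placebo must be a positive integer, got {self.n_placebo}")
        self.n_placebo = int(self.n_placebo)
        if self.n_abstinent is None and self.abstinence_rate is None:
            raise RecordValidationError(sid, "needs n_abstinent or abstinence_rate")
        if self.n_abstinent is not None:
            if self.n_abstinent < 0 or int(self.n_abstinent) != self.n_abstinent:
                raise RecordValidationError(sid, f"n_abstinent must be a non-negative integer, got {self.n_abstinent}")
            self.n_abstinent = int(self.n_abstinent)
            if self.n_abstinent > self.n_placebo:
                raise RecordValidationError(
                    sid, f"n_abstinent={self.n_abstinent} exceeds n_placebo={self.n_placebo}"
                )
            implied = self.n_abstinent / self.n_placebo
            if self.abstinence_rate is not None and abs(self.abstinence_rate - implied) > 5e-4:
                # counts are the primary datum (they drive the binomial variance)
                logger.warning(
                    "study %r: reported abstinence_rate %.4f disagrees with "
                    "n_abstinent/n_placebo = %.4f beyond rounding; using the counts",
                    sid, self.abstinence_rate, implied,
                )
            self.abstinence_rate = implied
        if not (0.0 <= self.abstinence_rate <= 1.0):
            raise RecordValidationError(sid, f"abstinence_rate {self.abstinence_rate} outside [0, 1]")
        if not (0.0 < self.duration_months <= 24.0):
            raise RecordValidationError(
                sid, f"duration_months {self.duration_months} outside (0, 24]"
            )
        if self.consumption_unit not in (GRAMS_PER_DAY, DRINKS_PER_DAY):
            raise RecordValidationError(sid, f"unknown consumption_unit {self.consumption_unit!r}")
        if self.consumption_unit == DRINKS_PER_DAY and not self.country:
            raise RecordValidationError(sid, "country is required when consumption is in drinks/day")
        if self.consumption_mean <= 0:
            raise RecordValidationError(sid, f"consumption_mean must be positive, got {self.consumption_mean}")
        if self.consumption_sd < 0:
            raise RecordValidationError(sid, f"consumption_sd must be non-negative, got {self.consumption_sd}")
        if self.abstinence_days_mean is not None and self.abstinence_days_mean < 0:
            raise RecordValidationError(sid, "abstinence_days_mean must be non-negative")
        if self.abstinence_days_sd is not None and self.abstinence_days_sd < 0:
            raise RecordValidationError(sid, "abstinence_days_sd must be non-negative")
        if self.pct_male is not None and not (0.0 <= self.pct_male <= 1.0):
            raise RecordValidationError(sid, f"pct_male {self.pct_male} outside [0, 1]")


def abstinence_rate(record: StudyRecord) -> float:
    """Continuous-abstinence proportion of the placebo arm.

    Recomputed from counts when available, otherwise the reported rate is
    taken as printed.
    """
    if record.n_abstinent is not None:
        return record.n_abstinent / record.n_placebo
    if record.abstinence_rate is None:
        raise RecordValidationError(record.study_id, "no abstinence information present")
    return record.abstinence_rate


def drinks_to_grams(
    drinks_per_day: float,
    country: str,
    table: DrinkConversionTable | None = None,
) -> float:
    """Convert standard drinks/day to g pure alcohol/day for a country."""
    if drinks_per_day < 0:
        raise ValueError(f"drinks_per_day must be non-negative, got {drinks_per_day}")
    table = table or DrinkConversionTable()
    return drinks_per_day * table[country]


def normalize_units(record: StudyRecord, table: DrinkConversionTable | None = None) -> StudyRecord:
    """Return a record with consumption expressed in g/day (idempotent)."""
    if record.consumption_unit == GRAMS_PER_DAY:
        return record
    table = table or DrinkConversionTable()
    factor = table[record.country]
    return replace(
        record,
        consumption_mean=record.consumption_mean * factor,
        consumption_sd=record.consumption_sd * factor,
        consumption_unit=GRAMS_PER_DAY,
    )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(round(v))


def read_study_table(
    path: str | Path,
    conversion_table: DrinkConversionTable | None = None,
    normalize: bool = True,
) -> list[StudyRecord]:
    """Read and validate an extraction-table CSV (one row per placebo arm).

    The CSV is comma-separated UTF-8 with a mandatory header row and "."
    as the decimal separator.  See :data:`CSV_COLUMNS` for the recognized
    columns.  Row order is preserved.

    Raises
    ------
    SchemaError
        if a mandatory column is absent.
    RecordValidationError
        if a row violates a record invariant (named by study_id).
    """
    df = pd.read_csv(path, dtype={"study_id": str, "country": str, "consumption_unit": str})
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if "n_abstinent" not in df.columns and "abstinence_rate" not in df.columns:
        raise SchemaError("missing mandatory column(s): n_abstinent or abstinence_rate")

    records = []
    for _, row in df.iterrows():
        def get(col):
            return row[col] if col in df.columns else None

        unit = get("consumption_unit")
        unit = GRAMS_PER_DAY if unit is None or (isinstance(unit, float) and math.isnan(unit)) else str(unit)
        country = get("country")
        if isinstance(country, float) and math.isnan(country):
            country = None
        rec = StudyRecord(
            study_id=str(row["study_id"]),
            n_placebo=_opt_int(row["n_placebo"]),
            n_abstinent=_opt_int(get("n_abstinent")),
            abstinence_rate=_opt_float(get("abstinence_rate")),
            duration_months=float(row["duration_months"]),
            consumption_mean=float(row["consumption_mean"]),
            consumption_sd=float(row["consumption_sd"]),
            consumption_unit=unit,
            country=country,
            abstinence_days_mean=_opt_float(get("abstinence_days_mean")),
            abstinence_days_sd=_opt_float(get("abstinence_days_sd")),
            detox_max_days=_opt_float(get("detox_max_days")),
            detox_min_days=_opt_float(get("detox_min_days")),
            pct_male=_opt_float(get("pct_male")),
            mean_age=_opt_float(get("mean_age")),
        )
        if normalize:
            rec = normalize_units(rec, conversion_table)
        records.append(rec)
    return records


def records_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    """Tabulate records in the canonical CSV column order."""
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in CSV_COLUMNS})
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_study_table(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write records to CSV; a round-trip through read preserves all fields."""
    records_to_frame(records).to_csv(path, index=False)
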