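"""Supplemental folic acid from 30-day supplement reports.

Each report covers one product: folic acid per serving, the number of days
it was taken in the past 30, and servings per day.  The person's average
daily supplemental folic acid is the 30-day average totalled over products,
and is treated as a constant daily amount added to every recall day.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "average_daily_supplement_fa",
    "flag_supplement_user",
    "add_supplement_to_days",
]

SUPPLEMENT_COLUMNS = (
    "person_id",
    "fa_per_serving_ug",
    "days_taken_past30",
    "servings_per_day",
)


def _validate_reports(reports: pd.DataFrame) -> None:
    missing = [c for c in SUPPLEMENT_COLUMNS if c not in reports.columns]
    if missing:
        raise DataError(f"supplement table missing columns: {missing}")
    days = reports["days_taken_past30"]
    if (days < 0).any() or (days > 30).any():
        raise DataError("days_taken_past30 must lie in [0, 30]")
    if (reports["fa_per_serving_ug"] < 0).any():
        raise DataError("fa_per_serving_ug must be >= 0")
    if (reports["servings_per_day"] < 0).any():
        raise DataError("servings_per_day must be >= 0")


def average_daily_supplement_fa(reports: pd.DataFrame) -> pd.Series:
    """Average daily supplemental folic acid (µg/day) per person.

    Each product contributes ``fa_per_serving_ug * servings_per_day *
    days_taken_past30 / 30``; products are summed within person.  Persons
    absent from the table simply have no entry (downstream joins fill 0).
    """
    _validate_reports(reports)
    per_report = (
        reports["fa_per_serving_ug"]
        * reports["servings_per_day"]
        * reports["days_taken_past30"]
        / 30.0
    )
    out = per_report.groupby(reports["person_id"]).sum()
    out.name = "supplement_fa_ug"
    return out


def flag_supplement_user(reports: pd.DataFrame) -> pd.Series:
    """Per-person flag: took a folic-acid-containing supplement in the past 30 days.

    True iff any report has at least one day of use and a positive folic
    acid content per serving.
    """
    _validate_reports(reports)
    used = (reports["days_taken_past30"] >= 1) & (reports["fa_per_serving_ug"] > 0)
    flag = used.groupby(reports["person_id"]).any()
    flag.name = "supplement_user"
    return flag


def add_supplement_to_days(
    person_days: pd.DataFrame, daily_supplement_fa: pd.Series
) -> pd.DataFrame:
    """Add each person's constant daily supplement amount to their day totals.

    Returns a copy of ``person_days`` with a ``supplement_fa_ug`` column and
    a ``total_fa_ug`` column equal to food + modeled added + supplement.
    Supplement-table persons absent from the recall table are ignored with a
    warning (they contribute no recall days to model).
    """
    if (daily_supplement_fa < 0).any():
        raise DataError("daily supplement folic acid must be >= 0")
    out = person_days.copy()
    supp = daily_supplement_fa.reindex(out["person_id"].unique())
    orphans = set(daily_supplement_fa.index) - set(out["person_id"].unique())
    if orphans:
        warnings.warn(
            f"{len(orphans)} person(s) in the supplement table have no recall days",
            stacklevel=2,
        )
    out["supplement_fa_ug"] = (
        out["person_id"].map(daily_supplement_fa).fillna(0.0).astype(float)
    )
    added = out["added_fa_ug"] if "added_fa_ug" in out.columns else 0.0
    out["total_fa_ug"] = out["food_fa_ug"] + added + out["supplement_fa_ug"]
    return out
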