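"""Analytic cohort assembly: exclusions, strata, and UL cut-points.

The tolerable upper intake level (UL) for folic acid is age-specific:
300 µg/day at ages 1-3, 400 at 4-8, 600 at 9-13, 800 at 14-18 and
1,000 µg/day for adults aged 19 and older.  Intake of naturally occurring
food folate is not part of the UL; only synthetic folic acid (fortified
foods plus supplements) counts.

Exclusions are applied in a fixed cascade — pregnancy, failed dietary
recall quality, missing supplement information, implausibly high
supplemental intake (>= 93 mg/day) — with each person attributed to the
first rule that removes them, and the cascade recorded in a ledger.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

__all__ = [
    "UL_SCHEDULE",
    "IMPLAUSIBLE_SUPPLEMENT_UG",
    "ExclusionLedger",
    "ul_for_age",
    "apply_exclusions",
    "assign_strata",
    "AGE_GROUPS",
    "RACE_ETHNICITY_REPORTED",
]

logger = logging.getLogger(__name__)

#: Age-specific UL schedule: (lower age bound inclusive, upper bound inclusive, µg/day).
UL_SCHEDULE: tuple[tuple[int, float, float], ...] = (
    (1, 3, 300.0),
    (4, 8, 400.0),
    (9, 13, 600.0),
    (14, 18, 800.0),
    (19, float("inf"), 1000.0),
)

#: Supplemental intake at or above this (µg/day) is treated as implausible.
IMPLAUSIBLE_SUPPLEMENT_UG = 93_000.0

#: Age-group labels used for stratified outputs.
AGE_GROUPS: tuple[tuple[str, int, float], ...] = (
    ("1-3", 1, 3),
    ("4-8", 4, 8),
    ("9-13", 9, 13),
    ("14-18", 14, 18),
    ("19-30", 19, 30),
    ("31-50", 31, 50),
    ("51-70", 51, 70),
    (">70", 71, float("inf")),
)

#: Race/ethnicity groups reported in stratified tables; all groups are kept
#: in totals, but race/ethnicity-stratified outputs are restricted to these.
RACE_ETHNICITY_REPORTED = (
    "Non-Hispanic white",
    "Non-Hispanic black",
    "Mexican American",
)


def ul_for_age(age_years: float) -> float:
    """UL cut-point (µg folic acid/day) for a given age in whole years.

    The UL is undefined below age 1 (infants are excluded from UL analyses).
    Bracket boundaries are closed on the left: age 19 is adult.
    """
    if age_years < 1:
        raise DomainError(f"UL not defined for age {age_years} (< 1 year)")
    for lo, hi, cut in UL_SCHEDULE:
        if lo <= age_years <= hi:
            return cut
    raise DomainError(f"no UL bracket for age {age_years}")  # pragma: no cover


def age_group_label(age_years: float) -> str | None:
    """Stratification age-group label, or None for infants (< 1 year)."""
    for label, lo, hi in AGE_GROUPS:
        if lo <= age_years <= hi:
            return label
    return None


@dataclass
class ExclusionLedger:
    """Ordered record of the exclusion cascade."""

    initial_n: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def final_n(self) -> int:
        return self.initial_n - sum(n for _, n in self.steps)

    @property
    def ratio_to_total_sampled(self) -> float:
        """final n / total sampled n (the '% of eligible sample' convention)."""
        return self.final_n / self.initial_n

    @property
    def ratio_to_post_pregnancy(self) -> float:
        """final n / n remaining after the pregnancy exclusion."""
        removed_pregnant = dict(self.steps).get("pregnant", 0)
        return self.final_n / (self.initial_n - removed_pregnant)

    def to_dict(self) -> dict:
        return {
            "initial_n": self.initial_n,
            "steps": [{"rule": r, "n_removed": n} for r, n in self.steps],
            "final_n": self.final_n,
            "ratio_to_total_sampled": self.ratio_to_total_sampled,
            "ratio_to_post_pregnancy": self.ratio_to_post_pregnancy,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        lines = [f"analytic sample: initial n = {self.initial_n:,}"]
        for rule, n in self.steps:
            lines.append(f"  - excluded ({rule}): {n:,}")
        lines.append(
            f"final n = {self.final_n:,} "
            f"({100 * self.ratio_to_total_sampled:.0f}% of total sampled; "
            f"{100 * self.ratio_to_post_pregnancy:.0f}% of the non-pregnant sample)"
        )
        return "\n".join(lines)


def apply_exclusions(
    participants: pd.DataFrame,
    daily_supplement_fa: pd.Series | None = None,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the analytic exclusion cascade and return (cohort, ledger).

    Rules, in order; a person is attributed to the first rule that removes
    them:

    1. ``pregnant`` — currently pregnant at interview.
    2. ``recall_quality`` — day-1 recall failed quality standards, or day-2
       failed for persons with a day-2 recall (one-day-cycle persons have no
       day-2 requirement; a missing/NA day-2 flag means no day 2).
    3. ``missing_supplement_info`` — supplement-use information absent.
    4. ``implausible_supplement`` — average daily supplemental folic acid
       at or above 93 mg (93,000 µg).
    """
    df = participants
    ledger = ExclusionLedger(initial_n=len(df))
    alive = pd.Series(True, index=df.index)

    pregnant = df["pregnant"].fillna(False).astype(bool)
    hit = alive & pregnant
    ledger.steps.append(("pregnant", int(hit.sum())))
    alive &= ~hit

    bad_day1 = ~df["recall_quality_ok_day1"].fillna(False).astype(bool)
    if "recall_quality_ok_day2" in df.columns:
        d2 = df["recall_quality_ok_day2"]
        has_day2 = d2.notna()
        bad_day2 = has_day2 & ~d2.fillna(True).astype(bool)
    else:
        bad_day2 = pd.Series(False, index=df.index)
    hit = alive & (bad_day1 | bad_day2)
    ledger.steps.append(("recall_quality", int(hit.sum())))
    alive &= ~hit

    missing_supp = ~df["supplement_info_present"].fillna(False).astype(bool)
    hit = alive & missing_supp
    ledger.steps.append(("missing_supplement_info", int(hit.sum())))
    alive &= ~hit

    if daily_supplement_fa is not None:
        supp = df["person_id"].map(daily_supplement_fa).fillna(0.0)
        hit = alive & (supp >= IMPLAUSIBLE_SUPPLEMENT_UG)
    else:
        hit = alive & False
    ledger.steps.append(("implausible_supplement", int(hit.sum())))
    alive &= ~hit

    cohort = df[alive].copy()
    if (cohort["weight"] <= 0).any():
        raise DataError("included persons must have positive analytic weight")
    for line in str(ledger).splitlines():
        logger.info(line)
    return cohort, ledger


def assign_strata(participants: pd.DataFrame) -> pd.DataFrame:
    """Attach stratification labels to a participant table.

    Adds ``age_group`` (None for infants), ``race_ethnicity_reported``
    (the race/ethnicity label if it is one of the three reported groups,
    else NA — such persons stay in totals but are absent from
    race/ethnicity-stratified tables), and ``sex`` is validated as present.
    Persons missing a demographic are excluded from that stratification
    only, with a log message.
    """
    out = participants.copy()
    if "sex" not in out.columns or "age_years" not in out.columns:
        raise DataError("participants need 'sex' and 'age_years' columns")
    out["age_group"] = out["age_years"].map(age_group_label)
    n_infant = int(out["age_group"].isna().sum())
    if n_infant:
        logger.info("%d person(s) under 1 year: no age-group stratum", n_infant)
    race = out["race_ethnicity"].where(
        out["race_ethnicity"].isin(RACE_ETHNICITY_REPORTED)
    )
    out["race_ethnicity_reported"] = race
    n_other = int(race.isna().sum())
    if n_other:
        logger.info(
            "%d person(s) outside the three reported race/ethnicity groups: "
            "included in totals only",
            n_other,
        )
    return out
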