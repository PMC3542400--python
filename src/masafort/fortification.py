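"""Fortification scenarios for corn masa flour.

A scenario is a fortificant level (µg folic acid per 100 g of corn masa
flour) together with the set of survey food codes whose products could
contain corn masa flour.  The grams of corn masa flour in a reported food
are proxied by the food's non-wholegrain gram content, so the folic acid
added to one recall row is simply ``nonwholegrain_g * level / 100``.

The packaged food-code list (``data/corn_masa_food_codes_synthetic.txt``)
is a synthetic stand-in with the size and code style of the expert-validated
corn-masa food list; it pairs with the synthetic survey generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

__all__ = [
    "FortificationScenario",
    "compute_added_folic_acid",
    "apply_scenario",
    "flag_corn_masa_consumers",
    "load_packaged_food_codes",
]

#: Default fortificant level, µg folic acid per 100 g corn masa flour.
DEFAULT_LEVEL_UG_PER_100G = 140.0

#: Columns a recall table must provide.
RECALL_COLUMNS = (
    "person_id",
    "day_index",
    "food_code",
    "amount_g",
    "folic_acid_ug",
    "nonwholegrain_g",
    "day_of_week",
    "interview_mode",
)


def load_packaged_food_codes() -> frozenset[str]:
    """Return the packaged (synthetic) corn-masa food-code set."""
    text = (
        resources.files("masafort.data")
        .joinpath("corn_masa_food_codes_synthetic.txt")
        .read_text()
    )
    codes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codes.append(line.split("\t")[0])
    return frozenset(codes)


@dataclass(frozen=True)
class FortificationScenario:
    """Fortificant level plus the matched food-code set.

    An empty food-code set or a level of 0 is the null scenario: it adds
    no folic acid and reproduces current intake exactly.
    """

    level_ug_per_100g: float = DEFAULT_LEVEL_UG_PER_100G
    corn_masa_food_codes: frozenset[str] = field(
        default_factory=load_packaged_food_codes
    )

    def __post_init__(self) -> None:
        if self.level_ug_per_100g < 0:
            raise DomainError(
                f"level_ug_per_100g must be >= 0, got {self.level_ug_per_100g}"
            )
        object.__setattr__(
            self, "corn_masa_food_codes", frozenset(self.corn_masa_food_codes)
        )

    @classmethod
    def null(cls) -> "FortificationScenario":
        """The scenario with no fortification (current intake)."""
        return cls(level_ug_per_100g=0.0, corn_masa_food_codes=frozenset())

    @classmethod
    def from_files(
        cls, level_ug_per_100g: float, food_list_path: str | Path
    ) -> "FortificationScenario":
        """Build a scenario from a plain-text food-code list (one code per line)."""
        codes = []
        for line in Path(food_list_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codes.append(line.split("\t")[0])
        return cls(level_ug_per_100g=level_ug_per_100g, corn_masa_food_codes=frozenset(codes))


def compute_added_folic_acid(nonwholegrain_g, level_ug_per_100g):
    """Folic acid (µg) added to a food by fortifying its corn masa flour.

    ``nonwholegrain_g`` grams of corn masa flour (proxied by non-wholegrain
    content) fortified at ``level_ug_per_100g`` µg per 100 g contribute
    ``nonwholegrain_g * level_ug_per_100g / 100`` µg.  For example 32 g at
    140 µg/100 g yields 44.8 µg.  Accepts scalars or arrays.
    """
    g = np.asarray(nonwholegrain_g, dtype=float)
    if np.any(g < 0):
        raise DomainError("nonwholegrain_g must be >= 0")
    if level_ug_per_100g < 0:
        raise DomainError("level_ug_per_100g must be >= 0")
    out = g * (level_ug_per_100g / 100.0)
    if np.isscalar(nonwholegrain_g) or np.ndim(nonwholegrain_g) == 0:
        return float(out)
    return out


def _validate_recall(recall: pd.DataFrame) -> None:
    missing = [c for c in RECALL_COLUMNS if c not in recall.columns]
    if missing:
        raise DataError(f"recall table missing columns: {missing}")
    days = recall["day_index"].unique()
    bad = set(days) - {1, 2}
    if bad:
        raise DataError(f"unknown day_index values: {sorted(bad)}")
    if (recall["folic_acid_ug"] < 0).any():
        raise DataError("folic_acid_ug must be >= 0")
    if (recall["nonwholegrain_g"] < 0).any():
        raise DataError("nonwholegrain_g must be >= 0")


def apply_scenario(
    recall: pd.DataFrame, scenario: FortificationScenario
) -> pd.DataFrame:
    """Collapse recall rows to person-day intakes under a fortification scenario.

    Returns one row per (person_id, day_index) with

    - ``food_fa_ug``: total reported folic acid from foods that day,
    - ``added_fa_ug``: modeled folic acid from fortified corn masa flour,
      summed over rows whose food code is in the scenario's matched set,
    - ``day_of_week`` and ``interview_mode`` carried through (first row of
      the day; both are recorded per day, not per food).
    """
    _validate_recall(recall)
    rows = recall.copy()
    matched = rows["food_code"].astype(str).isin(scenario.corn_masa_food_codes)
    rows["added_fa_ug"] = 0.0
    if scenario.level_ug_per_100g > 0 and matched.any():
        rows.loc[matched, "added_fa_ug"] = compute_added_folic_acid(
            rows.loc[matched, "nonwholegrain_g"].to_numpy(),
            scenario.level_ug_per_100g,
        )
    out = (
        rows.groupby(["person_id", "day_index"], sort=True)
        .agg(
            food_fa_ug=("folic_acid_ug", "sum"),
            added_fa_ug=("added_fa_ug", "sum"),
            day_of_week=("day_of_week", "first"),
            interview_mode=("interview_mode", "first"),
        )
        .reset_index()
    )
    return out


def flag_corn_masa_consumers(
    recall: pd.DataFrame, scenario: FortificationScenario
) -> pd.Series:
    """Per-person flag: consumed a matched corn-masa food on day 1 or day 2.

    Indexed by person_id; covers every person present in the recall table.
    """
    _validate_recall(recall)
    matched = recall["food_code"].astype(str).isin(scenario.corn_masa_food_codes)
    flag = matched.groupby(recall["person_id"]).any()
    flag.name = "corn_masa_consumer"
    return flag
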