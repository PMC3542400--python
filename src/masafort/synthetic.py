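"""Seeded synthetic survey populations with NHANES-like dietary structure.

The generator emulates the features of a two-recall-day national dietary
survey that the downstream analysis relies on:

- usual food folic-acid intake lognormal across persons (between-person
  log-scale SD) with lognormal day-to-day fluctuation around each person's
  usual level (within-person log-scale SD);
- two 24-hour recall days for most persons, one day for a configurable
  fraction (emulating the earliest survey cycle, which collected a single
  recall);
- a day-of-week effect (multiplicative weekend bump) and an interview-mode
  effect (day 2 by telephone), giving the covariate adjustment real signal
  to remove;
- a supplement-user subpopulation with person-constant daily supplemental
  folic acid built from per-product 30-day reports;
- corn-masa-food consumption concentrated in one race/ethnicity stratum,
  with non-wholegrain grams (the corn-masa proxy) drawn per person;
- positive analytic weights with a full set of delete-one-group jackknife
  replicate weights.

Every draw flows from one seed, so a fixed config reproduces the tables
byte-for-byte.  Alongside the tables the generator returns a
:class:`SyntheticTruth` holding each person's true usual intake and the
true population fractions above the UL cut-points, the ground truth that
recovery tests measure against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fortification import load_packaged_food_codes
from .cohort import UL_SCHEDULE

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SurveyTables",
    "generate_survey",
    "generate_replicate_weights",
    "write_survey",
]

#: Food code used for the aggregate non-corn-masa food row on each day.
GENERIC_FOOD_CODE = "99999999"

_RACE_LEVELS = (
    "Non-Hispanic white",
    "Non-Hispanic black",
    "Mexican American",
    "Other",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic survey population.

    Log-scale variance defaults are illustrative round values for a
    fortified-food nutrient, not calibrated to any survey release; see the
    methods note.  ``nonwholegrain_g_dist`` is (meanlog, sdlog) of the
    lognormal for a consumer's non-wholegrain grams per corn-masa food
    occurrence (held constant within person across days).
    """

    n_persons: int = 5000
    frac_one_day: float = 0.25
    mu_log_food_fa: float = 5.2
    sigma_between: float = 0.5
    sigma_within: float = 0.6
    weekend_bump: float = 0.10
    telephone_effect: float = -0.03
    supplement_user_prob: float = 0.342
    supplement_dose_dist: dict[float, float] = field(
        default_factory=lambda: {200.0: 0.20, 400.0: 0.70, 800.0: 0.08, 1000.0: 0.02}
    )
    daily_use_prob: float = 0.6
    race_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Non-Hispanic white": 0.45,
            "Non-Hispanic black": 0.22,
            "Mexican American": 0.22,
            "Other": 0.11,
        }
    )
    corn_masa_consumer_prob_by_stratum: dict[str, float] = field(
        default_factory=lambda: {
            "Mexican American": 0.65,
            "Non-Hispanic white": 0.25,
            "Non-Hispanic black": 0.25,
            "Other": 0.30,
        }
    )
    nonwholegrain_g_dist: tuple[float, float] = (3.2, 0.6)
    pregnant_prob: float = 0.03
    quality_fail_prob: float = 0.03
    supplement_info_missing_prob: float = 0.01
    implausible_supplement_prob: float = 0.0004
    age_min: int = 1
    age_max: int = 85
    n_replicates: int = 122
    truth_fortification_level: float = 140.0
    seed: int = 0

    def validate(self) -> None:
        def _prop(name: str) -> None:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")

        if self.n_persons < 1:
            raise ConfigurationError(f"n_persons must be >= 1, got {self.n_persons}")
        for name in (
            "frac_one_day",
            "supplement_user_prob",
            "daily_use_prob",
            "pregnant_prob",
            "quality_fail_prob",
            "supplement_info_missing_prob",
            "implausible_supplement_prob",
        ):
            _prop(name)
        for name in ("sigma_between", "sigma_within"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_replicates < 2:
            raise ConfigurationError(
                f"n_replicates must be >= 2, got {self.n_replicates}"
            )
        if self.n_replicates > self.n_persons:
            raise ConfigurationError(
                f"n_replicates ({self.n_replicates}) exceeds n_persons ({self.n_persons})"
            )
        for name, dist in (
            ("supplement_dose_dist", self.supplement_dose_dist),
            ("race_probs", self.race_probs),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError(f"{name} contains a negative probability")
        if any(d < 0 for d in self.supplement_dose_dist):
            raise ConfigurationError("supplement_dose_dist contains a negative dose")
        missing = set(self.race_probs) - set(self.corn_masa_consumer_prob_by_stratum)
        if missing:
            raise ConfigurationError(
                f"corn_masa_consumer_prob_by_stratum missing strata: {sorted(missing)}"
            )
        for stratum, p in self.corn_masa_consumer_prob_by_stratum.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"corn_masa_consumer_prob_by_stratum[{stratum!r}] must lie in [0, 1]"
                )
        if self.truth_fortification_level < 0:
            raise ConfigurationError("truth_fortification_level must be >= 0")
        if not (1 <= self.age_min <= self.age_max):
            raise ConfigurationError("require 1 <= age_min <= age_max")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["supplement_dose_dist"] = {str(k): v for k, v in self.supplement_dose_dist.items()}
        d["nonwholegrain_g_dist"] = list(self.nonwholegrain_g_dist)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth underlying one generated survey.

    ``persons`` has one row per person: ``person_id``, ``true_food_usual_ug``
    (expected day intake at the reference covariate level: weekday,
    in-person), ``true_supplement_ug``, ``corn_masa_consumer`` and
    ``nonwholegrain_g`` (daily grams of the corn-masa proxy; 0 for
    non-consumers).  ``frac_above`` maps each UL cut-point to the weighted
    population fraction above it under the current and fortified scenarios
    (fortified at ``fortification_level`` µg/100 g).
    """

    persons: pd.DataFrame
    weights: pd.Series
    fortification_level: float
    frac_above: dict[float, dict[str, float]]

    def true_usual_total(self, scenario_level: float = 0.0) -> pd.Series:
        """Per-person true usual total intake (µg/day) at a fortificant level."""
        p = self.persons
        added = (
            p["nonwholegrain_g"]
            * p["corn_masa_consumer"].astype(float)
            * scenario_level
            / 100.0
        )
        out = p["true_food_usual_ug"] + p["true_supplement_ug"] + added
        out.index = p["person_id"]
        out.name = "true_usual_total_ug"
        return out

    def fraction_above(
        self,
        cutpoint: float,
        scenario_level: float = 0.0,
        person_ids=None,
    ) -> float:
        """Weighted fraction of (a subset of) persons with true usual intake > cutpoint."""
        total = self.true_usual_total(scenario_level)
        w = self.weights.copy()
        w.index = self.persons["person_id"]
        if person_ids is not None:
            total = total.loc[person_ids]
            w = w.loc[person_ids]
        return float(np.average(total > cutpoint, weights=w))

    def to_json(self, **kwargs) -> str:
        payload = {
            "fortification_level": self.fortification_level,
            "frac_above": {
                str(int(c)): v for c, v in sorted(self.frac_above.items())
            },
            "n_persons": int(len(self.persons)),
        }
        return json.dumps(payload, **kwargs)


class SurveyTables(NamedTuple):
    demographics: pd.DataFrame
    recall: pd.DataFrame
    supplements: pd.DataFrame
    truth: SyntheticTruth


def generate_replicate_weights(
    base_weights: np.ndarray, n_replicates: int, seed: int
) -> np.ndarray:
    """Delete-one-group jackknife replicate weights.

    Persons are partitioned at random into ``n_replicates`` pseudo-groups of
    near-equal size.  Replicate column r zeroes the weights of group r and
    rescales the remaining weights by a common factor so that every column
    sums to the base weight total.
    """
    w = np.asarray(base_weights, dtype=float)
    if np.any(w <= 0):
        raise ConfigurationError("base weights must be > 0")
    n = len(w)
    if n_replicates < 2:
        raise ConfigurationError(f"n_replicates must be >= 2, got {n_replicates}")
    if n_replicates > n:
        raise ConfigurationError(
            f"n_replicates ({n_replicates}) exceeds n_persons ({n})"
        )
    rng = np.random.default_rng(seed)
    group = rng.permutation(n) % n_replicates
    total = w.sum()
    out = np.empty((n, n_replicates))
    for r in range(n_replicates):
        dropped = group == r
        kept_total = total - w[dropped].sum()
        col = w * (total / kept_total)
        col[dropped] = 0.0
        out[:, r] = col
    return out


def _day_intakes(cfg, rng, log_usual, n):
    """One day of observed food folic acid plus its covariate labels."""
    dow = rng.integers(1, 8, size=n)  # 1=Mon .. 7=Sun
    eps = rng.normal(0.0, cfg.sigma_within, size=n)
    fa = np.exp(log_usual + eps)
    fa = fa * np.where(dow >= 6, 1.0 + cfg.weekend_bump, 1.0)
    return fa, dow


def generate_survey(config: GeneratorConfig) -> SurveyTables:
    """Generate (demographics, recall, supplements, truth) for one config.

    Deterministic given the config (including its seed): identical inputs
    give byte-identical tables.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    person_id = np.array([f"P{i:06d}" for i in range(1, n + 1)])

    sex = np.where(rng.random(n) < 0.5, "Male", "Female")
    races = list(cfg.race_probs)
    race = rng.choice(races, size=n, p=[cfg.race_probs[r] for r in races])
    age = rng.integers(cfg.age_min, cfg.age_max + 1, size=n)
    one_day = rng.random(n) < cfg.frac_one_day
    cycle = np.where(
        one_day, "2001-2002", rng.choice(["2003-2004", "2005-2006", "2007-2008"], size=n)
    )
    pregnant = (
        (sex == "Female") & (age >= 15) & (age <= 44) & (rng.random(n) < cfg.pregnant_prob)
    )
    quality_ok_day1 = rng.random(n) >= cfg.quality_fail_prob
    quality_ok_day2 = np.where(
        one_day, np.nan, (rng.random(n) >= cfg.quality_fail_prob).astype(float)
    )
    supplement_info_present = rng.random(n) >= cfg.supplement_info_missing_prob
    weight = 100.0 * rng.lognormal(0.0, 0.5, size=n)
    rep = generate_replicate_weights(
        weight, cfg.n_replicates, seed=int(rng.integers(0, 2**31 - 1))
    )

    # usual food folic acid on the log scale
    log_usual = cfg.mu_log_food_fa + cfg.sigma_between * rng.normal(size=n)
    true_food_usual = np.exp(log_usual + 0.5 * cfg.sigma_within**2)

    # supplements: person-constant daily amount from per-product 30-day reports
    is_user = rng.random(n) < cfg.supplement_user_prob
    doses = np.array(list(cfg.supplement_dose_dist), dtype=float)
    dose = rng.choice(doses, size=n, p=list(cfg.supplement_dose_dist.values()))
    days = np.where(
        rng.random(n) < cfg.daily_use_prob, 30, rng.integers(1, 30, size=n)
    )
    implausible = rng.random(n) < cfg.implausible_supplement_prob
    dose = np.where(implausible, 100_000.0, dose)
    days = np.where(implausible, 30, days)
    is_user = is_user | implausible
    true_supp = np.where(is_user, dose * days / 30.0, 0.0)

    # corn masa consumption, concentrated by stratum
    p_masa = np.array([cfg.corn_masa_consumer_prob_by_stratum[r] for r in race])
    masa_consumer = rng.random(n) < p_masa
    meanlog, sdlog = cfg.nonwholegrain_g_dist
    masa_g = np.where(masa_consumer, rng.lognormal(meanlog, sdlog, size=n), 0.0)
    masa_codes = sorted(load_packaged_food_codes())
    masa_code = rng.choice(masa_codes, size=n)

    demographics = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "race_ethnicity": race,
            "age_years": age,
            "pregnant": pregnant,
            "cycle": cycle,
            "recall_quality_ok_day1": quality_ok_day1,
            "recall_quality_ok_day2": quality_ok_day2,
            "supplement_info_present": supplement_info_present,
            "weight": weight,
        }
    )
    rep_cols = pd.DataFrame(
        rep, columns=[f"rw_{r + 1}" for r in range(cfg.n_replicates)]
    )
    demographics = pd.concat([demographics, rep_cols], axis=1)

    # recall rows: one aggregate food row per day carrying the day's reported
    # folic acid, plus one corn-masa row (zero reported folic acid, positive
    # non-wholegrain grams) for consumers
    fa1, dow1 = _day_intakes(cfg, rng, log_usual, n)
    fa2, dow2 = _day_intakes(cfg, rng, log_usual, n)
    fa2 = fa2 * (1.0 + cfg.telephone_effect)
    two_day = ~one_day

    def _day_rows(day_index, fa, dow, mode, mask):
        generic = pd.DataFrame(
            {
                "person_id": person_id[mask],
                "day_index": day_index,
                "food_code": GENERIC_FOOD_CODE,
                "amount_g": 500.0,
                "folic_acid_ug": fa[mask],
                "nonwholegrain_g": 0.0,
                "day_of_week": dow[mask],
                "interview_mode": mode,
            }
        )
        mmask = mask & masa_consumer
        masa = pd.DataFrame(
            {
                "person_id": person_id[mmask],
                "day_index": day_index,
                "food_code": masa_code[mmask],
                "amount_g": 1.6 * masa_g[mmask],
                "folic_acid_ug": 0.0,
                "nonwholegrain_g": masa_g[mmask],
                "day_of_week": dow[mmask],
                "interview_mode": mode,
            }
        )
        return pd.concat([generic, masa], ignore_index=True)

    all_persons = np.ones(n, dtype=bool)
    recall = pd.concat(
        [
            _day_rows(1, fa1, dow1, "in_person", all_persons),
            _day_rows(2, fa2, dow2, "telephone", two_day),
        ],
        ignore_index=True,
    ).sort_values(["person_id", "day_index", "food_code"], kind="stable")
    recall = recall.reset_index(drop=True)

    supplements = pd.DataFrame(
        {
            "person_id": person_id[is_user],
            "fa_per_serving_ug": dose[is_user],
            "days_taken_past30": days[is_user],
            "servings_per_day": 1.0,
        }
    ).reset_index(drop=True)

    truth_persons = pd.DataFrame(
        {
            "person_id": person_id,
            "true_food_usual_ug": true_food_usual,
            "true_supplement_ug": true_supp,
            "corn_masa_consumer": masa_consumer,
            "nonwholegrain_g": masa_g,
        }
    )
    truth = SyntheticTruth(
        persons=truth_persons,
        weights=pd.Series(weight, name="weight"),
        fortification_level=cfg.truth_fortification_level,
        frac_above={},
    )
    cutpoints = sorted({cut for _, _, cut in UL_SCHEDULE})
    truth.frac_above = {
        cut: {
            "current": truth.fraction_above(cut, 0.0),
            "fortified": truth.fraction_above(cut, cfg.truth_fortification_level),
        }
        for cut in cutpoints
    }
    return SurveyTables(demographics, recall, supplements, truth)


def write_survey(tables: SurveyTables, outdir: str | Path, parquet: bool = False) -> None:
    """Write the three survey tables as CSV (optionally Parquet) plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("demographics", "recall", "supplements"):
        df: pd.DataFrame = getattr(tables, name)
        df.to_csv(outdir / f"{name}.csv", index=False)
        if parquet:
            df.to_parquet(outdir / f"{name}.parquet", index=False)
    (outdir / "truth.json").write_text(tables.truth.to_json(indent=2))
    tables.truth.persons.assign(weight=tables.truth.weights.to_numpy()).to_csv(
        outdir / "truth_persons.csv", index=False
    )
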