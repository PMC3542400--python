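"""End-to-end orchestration: generate/load → fortify → model → infer → tables.

A run takes either three survey tables on disk or a synthetic-survey
generator block, applies the exclusion cascade, computes person-day total
folic acid under the current (no fortification) and modeled (fortified corn
masa flour) scenarios, fits the usual-intake model, and emits three table
families:

- a demographics table (unweighted n, weighted %, corn-masa consumption and
  supplement use by stratum);
- adult UL exceedance (% with usual total folic acid ≥ 1,000 µg/day) by
  scenario, supplement use and stratum, with jackknife CIs and paired
  current-vs-modeled t-tests;
- child age-specific UL exceedance by age group and supplement use.

Within a run the transformation and covariate effects are estimated once on
the full cohort's current-scenario intakes and held fixed across strata and
scenarios; variance components are re-estimated per stratum (falling back
to the cohort values when a stratum has too few two-day persons) and shared
between the paired scenarios.  Sharing makes the scenario comparison
monotone by construction: fortification can only raise usual intakes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    AGE_GROUPS,
    RACE_ETHNICITY_REPORTED,
    apply_exclusions,
    assign_strata,
    ul_for_age,
    ExclusionLedger,
)
from .errors import ConfigurationError, MasafortError
from .fortification import (
    FortificationScenario,
    apply_scenario,
    flag_corn_masa_consumers,
)
from .supplements import (
    add_supplement_to_days,
    average_daily_supplement_fa,
    flag_supplement_user,
)
from .survey_stats import ReplicateEstimates, compare_scenarios, jackknife_se, weighted_proportion
from .synthetic import GeneratorConfig, SurveyTables, generate_survey
from .usual_intake import UsualIntakeModel, fit_usual_intake, percent_above, update_intakes

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "render_tables"]

logger = logging.getLogger(__name__)

ADULT_AGE_GROUPS = ("19-30", "31-50", "51-70", ">70")
CHILD_AGE_GROUPS = ("1-3", "4-8", "9-13", "14-18")


@dataclass
class RunConfig:
    """One pipeline run: exactly one of (input paths, generator) is set."""

    generator: GeneratorConfig | None = None
    demographics_csv: str | None = None
    recall_csv: str | None = None
    supplements_csv: str | None = None
    scenario_level: float = 140.0
    food_list_path: str | None = None
    ul_overrides: dict[str, float] = field(default_factory=dict)
    dow_levels: str = "weekend3"
    min_stratum_n: int = 10
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_paths = any(
            p is not None
            for p in (self.demographics_csv, self.recall_csv, self.supplements_csv)
        )
        if have_paths and self.generator is not None:
            raise ConfigurationError(
                "config must set input paths or a generator block, not both"
            )
        if have_paths and not all(
            (self.demographics_csv, self.recall_csv, self.supplements_csv)
        ):
            raise ConfigurationError(
                "all three of demographics_csv, recall_csv, supplements_csv are required"
            )
        if not have_paths and self.generator is None:
            raise ConfigurationError(
                "config must set input paths or a generator block"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        inputs = raw.pop("inputs", {}) or {}
        scenario = raw.pop("scenario", {}) or {}
        kwargs: dict = {}
        if gen is not None:
            if "supplement_dose_dist" in gen:
                gen["supplement_dose_dist"] = {
                    float(k): v for k, v in gen["supplement_dose_dist"].items()
                }
            if "nonwholegrain_g_dist" in gen:
                gen["nonwholegrain_g_dist"] = tuple(gen["nonwholegrain_g_dist"])
            kwargs["generator"] = GeneratorConfig(**gen)
        for key, attr in (
            ("demographics", "demographics_csv"),
            ("recall", "recall_csv"),
            ("supplements", "supplements_csv"),
        ):
            if key in inputs:
                kwargs[attr] = inputs[key]
        if "level_ug_per_100g" in scenario:
            kwargs["scenario_level"] = float(scenario["level_ug_per_100g"])
        if scenario.get("food_list_path"):
            kwargs["food_list_path"] = scenario["food_list_path"]
        kwargs.update(raw)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ResultBundle:
    """Everything one pipeline run produces."""

    seed: int
    scenario_level: float
    ledger: ExclusionLedger
    demographics_table: pd.DataFrame
    adult_exceedance: pd.DataFrame
    child_exceedance: pd.DataFrame
    model_summary: dict
    truth_frac_above: dict | None = None

    def hash(self) -> str:
        """SHA-256 over the rendered tables; equal configs+seeds give equal hashes."""
        h = hashlib.sha256()
        for df in (self.demographics_table, self.adult_exceedance, self.child_exceedance):
            h.update(df.to_csv(index=False).encode())
        h.update(self.ledger.to_json(sort_keys=True).encode())
        return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: logs timing, tags errors with the stage."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: %.2fs", name, dt)
                return False
            if isinstance(exc, MasafortError) and not getattr(exc, "_staged", False):
                exc._staged = True
                exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def _load_tables(config: RunConfig) -> SurveyTables | tuple:
    if config.generator is not None:
        gen = replace(config.generator, seed=config.seed)
        return generate_survey(gen)
    demographics = pd.read_csv(config.demographics_csv)
    recall = pd.read_csv(config.recall_csv, dtype={"food_code": str})
    supplements = pd.read_csv(config.supplements_csv)
    return SurveyTables(demographics, recall, supplements, None)


def _cell_cutpoint(config: RunConfig, group: str) -> float:
    if group in config.ul_overrides:
        return float(config.ul_overrides[group])
    rep_age = {"1-3": 2, "4-8": 6, "9-13": 11, "14-18": 16}.get(group, 25)
    return ul_for_age(rep_age)


def _exceedance_replicates(model: UsualIntakeModel, cutpoint: float, rw: pd.DataFrame):
    """Replicate re-estimates of % above, reusing the fitted usual values."""
    tab = model.person_table
    above = (tab["usual_ug"].to_numpy() > cutpoint).astype(float)
    W = rw.reindex(tab["person_id"]).to_numpy(dtype=float)
    col_tot = W.sum(axis=0)
    ok = col_tot > 0
    reps = np.full(W.shape[1], np.nan)
    reps[ok] = 100.0 * (above @ W[:, ok]) / col_tot[ok]
    if not ok.all():
        reps[~ok] = 100.0 * float(np.average(above, weights=model.weights.to_numpy()))
    return reps


def _exceedance_cells(cohort: pd.DataFrame):
    """Yield (age_panel, axis, stratum, member mask) for the stratified tables."""
    adult = cohort["age_years"] >= 19
    child = (cohort["age_years"] >= 1) & (cohort["age_years"] <= 18)
    yield "adult", "all", "Total", adult
    for s in ("Male", "Female"):
        yield "adult", "sex", s, adult & (cohort["sex"] == s)
    for r in RACE_ETHNICITY_REPORTED:
        yield "adult", "race_ethnicity", r, adult & (
            cohort["race_ethnicity_reported"] == r
        )
    for g in ADULT_AGE_GROUPS:
        yield "adult", "age_group", g, adult & (cohort["age_group"] == g)
    for g in CHILD_AGE_GROUPS:
        yield "child", "age_group", g, child & (cohort["age_group"] == g)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full analysis; deterministic given config + seed."""
    logging.basicConfig(level=config.log_level)

    with _stage("load"):
        tables = _load_tables(config)
        demographics, recall, supplements, truth = tables

    with _stage("supplements"):
        daily_supp = average_daily_supplement_fa(supplements)
        user_flag_all = flag_supplement_user(supplements)

    with _stage("exclusions"):
        cohort, ledger = apply_exclusions(demographics, daily_supp)
        cohort = assign_strata(cohort)
        cohort = cohort.set_index("person_id", drop=False)
        weights = cohort["weight"]
        rw_cols = [c for c in cohort.columns if c.startswith("rw_")]
        rw = cohort[rw_cols]

    with _stage("fortify"):
        if config.food_list_path:
            scenario = FortificationScenario.from_files(
                config.scenario_level, config.food_list_path
            )
        else:
            scenario = FortificationScenario(level_ug_per_100g=config.scenario_level)
        recall_c = recall[recall["person_id"].isin(cohort["person_id"])]
        days_current = apply_scenario(recall_c, FortificationScenario.null())
        days_modeled = apply_scenario(recall_c, scenario)
        supp_cohort = daily_supp.reindex(cohort["person_id"]).dropna()
        days_current = add_supplement_to_days(days_current, supp_cohort)
        days_modeled = add_supplement_to_days(days_modeled, supp_cohort)
        masa_flag = (
            flag_corn_masa_consumers(recall_c, scenario)
            .reindex(cohort["person_id"])
            .astype("boolean")
            .fillna(False)
            .astype(bool)
        )
        supp_user = (
            user_flag_all.reindex(cohort["person_id"])
            .astype("boolean")
            .fillna(False)
            .astype(bool)
        )

    with _stage("fit_full"):
        full_fit = fit_usual_intake(
            days_current, weights, dow_levels=config.dow_levels
        )

    with _stage("demographics_table"):
        demo_tab = _demographics_table(cohort, weights, rw, masa_flag, supp_user)

    with _stage("exceedance"):
        rows = []
        panels = (("total", pd.Series(True, index=cohort.index)), ("corn_masa_consumers", masa_flag))
        groups = (
            ("total", pd.Series(True, index=cohort.index)),
            ("nonusers", ~supp_user),
            ("users", supp_user),
        )
        days_by_person_cur = days_current.set_index("person_id", drop=False)
        days_by_person_mod = days_modeled.set_index("person_id", drop=False)
        for age_panel, axis, stratum, members in _exceedance_cells(cohort):
            cut = _cell_cutpoint(config, stratum if age_panel == "child" else "adult")
            for panel_name, panel_mask in panels:
                for group_name, group_mask in groups:
                    mask = members & panel_mask & group_mask
                    ids = cohort.loc[mask, "person_id"]
                    if len(ids) == 0:
                        logger.warning(
                            "empty stratum omitted: %s/%s/%s/%s",
                            panel_name, group_name, axis, stratum,
                        )
                        continue
                    if len(ids) < config.min_stratum_n:
                        logger.warning(
                            "stratum below min_stratum_n omitted (n=%d): %s/%s/%s/%s",
                            len(ids), panel_name, group_name, axis, stratum,
                        )
                        continue
                    row = _cell_estimates(
                        full_fit,
                        days_by_person_cur.loc[ids],
                        days_by_person_mod.loc[ids],
                        weights.loc[ids],
                        rw.loc[ids],
                        cut,
                    )
                    row.update(
                        panel=panel_name,
                        supp_group=group_name,
                        axis=axis,
                        stratum=stratum,
                        age_panel=age_panel,
                    )
                    rows.append(row)
        cols = [
            "age_panel", "panel", "supp_group", "axis", "stratum", "cutpoint_ug",
            "n_unweighted",
            "current_pct", "current_se", "current_lo", "current_hi", "current_ne",
            "modeled_pct", "modeled_se", "modeled_lo", "modeled_hi", "modeled_ne",
            "diff", "diff_se", "t", "p",
        ]
        exceed = pd.DataFrame(rows, columns=cols)
        adult_tab = exceed[exceed["age_panel"] == "adult"].drop(columns="age_panel").reset_index(drop=True)
        child_tab = exceed[exceed["age_panel"] == "child"].drop(columns="age_panel").reset_index(drop=True)

    bundle = ResultBundle(
        seed=config.seed,
        scenario_level=config.scenario_level,
        ledger=ledger,
        demographics_table=demo_tab,
        adult_exceedance=adult_tab,
        child_exceedance=child_tab,
        model_summary=full_fit.summary_dict(),
        truth_frac_above=(truth.frac_above if truth is not None else None),
    )
    if config.outdir:
        render_tables(bundle, config.outdir)
    return bundle


def _cell_estimates(full_fit, days_cur, days_mod, w, rw, cutpoint) -> dict:
    model_cur = update_intakes(full_fit, days_cur, w, reestimate_variances=True)
    model_mod = update_intakes(model_cur, days_mod, w, reestimate_variances=False)
    est_cur = percent_above(model_cur, cutpoint)
    est_mod = percent_above(model_mod, cutpoint)
    reps_cur = _exceedance_replicates(model_cur, cutpoint, rw)
    reps_mod = _exceedance_replicates(model_mod, cutpoint, rw)
    rep_cur = ReplicateEstimates(est_cur.percent_above, tuple(reps_cur))
    rep_mod = ReplicateEstimates(est_mod.percent_above, tuple(reps_mod))
    se_cur = jackknife_se(rep_cur)
    se_mod = jackknife_se(rep_mod)
    cmp = compare_scenarios(rep_cur, rep_mod, paired=True)
    return {
        "cutpoint_ug": cutpoint,
        "n_unweighted": est_cur.n_unweighted,
        "current_pct": est_cur.percent_above,
        "current_se": se_cur,
        "current_lo": max(0.0, est_cur.percent_above - 1.96 * se_cur),
        "current_hi": min(100.0, est_cur.percent_above + 1.96 * se_cur),
        "current_ne": est_cur.not_estimable,
        "modeled_pct": est_mod.percent_above,
        "modeled_se": se_mod,
        "modeled_lo": max(0.0, est_mod.percent_above - 1.96 * se_mod),
        "modeled_hi": min(100.0, est_mod.percent_above + 1.96 * se_mod),
        "modeled_ne": est_mod.not_estimable,
        "diff": cmp.difference,
        "diff_se": cmp.se,
        "t": cmp.t,
        "p": cmp.p,
    }


def _demographics_table(cohort, weights, rw, masa_flag, supp_user) -> pd.DataFrame:
    """Table-1-style weighted demographics of the analytic cohort."""
    rows = []
    cells = [("all", "Total", pd.Series(True, index=cohort.index))]
    for s in ("Male", "Female"):
        cells.append(("sex", s, cohort["sex"] == s))
    for r in RACE_ETHNICITY_REPORTED:
        cells.append(("race_ethnicity", r, cohort["race_ethnicity_reported"] == r))
    for g, _, _ in AGE_GROUPS:
        cells.append(("age_group", g, cohort["age_group"] == g))
    w_all = weights.to_numpy()
    for axis, stratum, mask in cells:
        if not mask.any():
            logger.warning("empty demographic stratum omitted: %s/%s", axis, stratum)
            continue
        pop = weighted_proportion(mask.to_numpy(), w_all, rw.to_numpy())
        sub_w = weights[mask].to_numpy()
        sub_rw = rw[mask].to_numpy()
        masa = weighted_proportion(masa_flag[mask.to_numpy()].to_numpy(), sub_w, sub_rw)
        supp = weighted_proportion(supp_user[mask.to_numpy()].to_numpy(), sub_w, sub_rw)
        rows.append(
            {
                "axis": axis,
                "stratum": stratum,
                "n_unweighted": int(mask.sum()),
                "weighted_pct": pop.percent,
                "weighted_pct_lo": pop.ci95[0],
                "weighted_pct_hi": pop.ci95[1],
                "corn_masa_pct": masa.percent,
                "corn_masa_lo": masa.ci95[0],
                "corn_masa_hi": masa.ci95[1],
                "supp_user_pct": supp.percent,
                "supp_user_lo": supp.ci95[0],
                "supp_user_hi": supp.ci95[1],
            }
        )
    return pd.DataFrame(rows)


def _fmt_cell(pct, lo, hi, ne) -> str:
    if ne:
        return "NE[a]"
    return f"{pct:.1f} ({lo:.1f}, {hi:.1f})"


def render_tables(bundle: ResultBundle, outdir: str | Path) -> None:
    """Write the result bundle as CSV files plus a human-readable text rendering.

    Cells whose tail-instability guard fired print as ``NE`` with a footnote
    in the text tables; the CSVs keep the numeric values alongside the
    boolean ``*_ne`` flags.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.demographics_table.to_csv(outdir / "demographics_table.csv", index=False)
    bundle.adult_exceedance.to_csv(outdir / "adult_exceedance.csv", index=False)
    bundle.child_exceedance.to_csv(outdir / "child_exceedance.csv", index=False)
    (outdir / "exclusion_ledger.json").write_text(bundle.ledger.to_json(indent=2))
    (outdir / "model_summary.json").write_text(json.dumps(bundle.model_summary, indent=2))
    meta = {
        "seed": bundle.seed,
        "scenario_level_ug_per_100g": bundle.scenario_level,
        "bundle_sha256": bundle.hash(),
    }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))

    lines = []
    lines.append("Exclusion cascade")
    lines.append(str(bundle.ledger))
    lines.append("")
    lines.append("Demographics (weighted %)")
    for _, r in bundle.demographics_table.iterrows():
        lines.append(
            f"  {r['axis']:>14} | {r['stratum']:>18} | n={r['n_unweighted']:>6} | "
            f"pop {r['weighted_pct']:.1f} ({r['weighted_pct_lo']:.1f}, {r['weighted_pct_hi']:.1f}) | "
            f"corn masa {r['corn_masa_pct']:.1f} | supp use {r['supp_user_pct']:.1f}"
        )
    for title, tab in (
        ("Adults: % above UL (1,000 µg/day unless overridden)", bundle.adult_exceedance),
        ("Children: % above age-specific UL", bundle.child_exceedance),
    ):
        lines.append("")
        lines.append(title)
        lines.append(
            "  panel | supp group | stratum | n | current % (95% CI) | modeled % (95% CI) | p"
        )
        for _, r in tab.iterrows():
            cur = _fmt_cell(r["current_pct"], r["current_lo"], r["current_hi"], r["current_ne"])
            mod = _fmt_cell(r["modeled_pct"], r["modeled_lo"], r["modeled_hi"], r["modeled_ne"])
            lines.append(
                f"  {r['panel']} | {r['supp_group']} | {r['stratum']} | "
                f"{r['n_unweighted']} | {cur} | {mod} | p={r['p']:.3f}"
            )
    lines.append("")
    lines.append("[a] NE = not estimable: too few persons beyond the cut-point for a stable tail estimate.")
    (outdir / "tables.txt").write_text("\n".join(lines) + "\n")
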