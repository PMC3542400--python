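"""Usual-intake model: transform round-trips, variance recovery, exceedance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from masafort import (
    DomainError,
    FortificationScenario,
    GeneratorConfig,
    ModelError,
    apply_scenario,
    back_transform,
    fit_usual_intake,
    generate_survey,
    percent_above,
    transform,
    update_intakes,
)


def _person_days(values_by_person, dow=3, mode="in_person"):
    rows = []
    for pid, vals in values_by_person.items():
        for d, v in enumerate(vals, start=1):
            rows.append(
                {"person_id": pid, "day_index": d, "total_fa_ug": v,
                 "day_of_week": dow, "interview_mode": mode}
            )
    return pd.DataFrame(rows)


def _weights(ids, value=1.0):
    return pd.Series(value, index=pd.Index(ids, name="person_id"))


@pytest.mark.parametrize("lam", [0.0, 1.0, 0.5, -0.5])
def test_back_transform_inverts_transform(lam):
    y = np.array([1.0, 10.0, 250.0, 1000.0])
    z = transform(y, lam, shift=0.0, scale=100.0)
    back = back_transform(lam, z, shift=0.0, scale=100.0)
    assert np.allclose(back, y, rtol=1e-10)


def test_log_and_identity_special_cases():
    assert back_transform(0.0, np.log(1000.0)) == pytest.approx(1000.0)
    assert back_transform(1.0, 41.0) == pytest.approx(42.0)  # (y-1)/1 = x


@given(
    lam=st.floats(min_value=-1.0, max_value=1.0),
    y=st.floats(min_value=0.5, max_value=5e3),
)
@settings(max_examples=150, deadline=None)
def test_round_trip_property(lam, y):
    lam = round(lam, 2)
    z = transform(y, lam, shift=0.0, scale=50.0)
    assert back_transform(lam, z, shift=0.0, scale=50.0) == pytest.approx(y, rel=1e-9)


def test_back_transform_domain_error():
    with pytest.raises(DomainError):
        back_transform(0.5, -10.0)  # lam*x + 1 <= 0


def test_constant_intake_is_degenerate():
    """Everyone reporting the same constant c has usual intake exactly c."""
    days = _person_days({f"P{i}": [250.0, 250.0] for i in range(20)})
    fit = fit_usual_intake(days, _weights([f"P{i}" for i in range(20)]))
    assert fit.sigma2_within == pytest.approx(0.0, abs=1e-18)
    assert fit.sigma2_between == pytest.approx(0.0, abs=1e-18)
    assert np.allclose(fit.person_table["usual_ug"], 250.0, rtol=1e-9)
    assert (fit.person_table["shrink_factor"] == 1.0).all()
    assert percent_above(fit, 100.0).percent_above == 100.0
    assert percent_above(fit, 1000.0).percent_above == 0.0


def test_no_two_day_subsample_requires_external_variance():
    days = _person_days({"A": [100.0], "B": [300.0]})
    w = _weights(["A", "B"])
    with pytest.raises(ModelError):
        fit_usual_intake(days, w)
    fit = fit_usual_intake(days, w, external_within_variance=0.1)
    assert fit.sigma2_within == pytest.approx(0.1)


def test_external_variance_equal_to_internal_estimate_changes_nothing():
    t = generate_survey(GeneratorConfig(n_persons=600, seed=12, frac_one_day=0.3))
    days = apply_scenario(t.recall, FortificationScenario.null())
    w = t.demographics.set_index("person_id")["weight"]
    base = fit_usual_intake(days, w, value_col="food_fa_ug")
    redo = fit_usual_intake(
        days, w, value_col="food_fa_ug",
        external_within_variance=base.sigma2_within,
    )
    assert redo.sigma2_within == base.sigma2_within
    assert redo.sigma2_between == pytest.approx(base.sigma2_between)
    pd.testing.assert_frame_equal(redo.person_table, base.person_table)


def test_variance_recovery_on_synthetic_survey():
    """Fitted between/within variances land within 3 MC SEs of generator truth."""
    cfg = GeneratorConfig(n_persons=5000, seed=21)
    t = generate_survey(cfg)
    days = apply_scenario(t.recall, FortificationScenario.null())
    w = t.demographics.set_index("person_id")["weight"]
    fit = fit_usual_intake(days, w, value_col="food_fa_ug")
    assert fit.lam == 0.0  # lognormal data: the grid picks the log
    n2 = int((fit.person_table["n_days"] == 2).sum())
    n = len(fit.person_table)
    s2w, s2b = cfg.sigma_within**2, cfg.sigma_between**2
    assert abs(fit.sigma2_within - s2w) < 3 * s2w * np.sqrt(2 / n2)
    assert abs(fit.sigma2_between - s2b) < 3 * np.sqrt(2 / n) * (s2b + s2w / 2)


def test_shrinkage_never_increases_spread(small_survey):
    days = apply_scenario(small_survey.recall, FortificationScenario.null())
    w = small_survey.demographics.set_index("person_id")["weight"]
    fit = fit_usual_intake(days, w, value_col="food_fa_ug")
    raw_var = np.var(fit.person_table["mean_transformed"])
    shrunk_var = np.var(fit.person_table["usual_transformed"])
    assert shrunk_var <= raw_var + 1e-12
    assert ((fit.person_table["shrink_factor"] > 0)
            & (fit.person_table["shrink_factor"] <= 1)).all()


def test_percent_above_monotone_in_cutpoint(small_survey):
    days = apply_scenario(small_survey.recall, FortificationScenario.null())
    w = small_survey.demographics.set_index("person_id")["weight"]
    fit = fit_usual_intake(days, w, value_col="food_fa_ug")
    cuts = [50, 100, 200, 400, 800, 1600]
    pcts = [percent_above(fit, c).percent_above for c in cuts]
    assert all(a >= b for a, b in zip(pcts, pcts[1:]))
    with pytest.raises(DomainError):
        percent_above(fit, 0.0)


def test_percent_above_matches_lognormal_closed_form():
    """Tail % within 1.5 points of 1 − Φ((ln c − µ)/σ) for lognormal truth."""
    cfg = GeneratorConfig(
        n_persons=5000, seed=31, mu_log_food_fa=6.5, sigma_between=0.4,
        sigma_within=0.2, supplement_user_prob=0.0, frac_one_day=0.0,
        weekend_bump=0.0, telephone_effect=0.0, pregnant_prob=0.0,
        quality_fail_prob=0.0, supplement_info_missing_prob=0.0,
        implausible_supplement_prob=0.0,
    )
    t = generate_survey(cfg)
    days = apply_scenario(t.recall, FortificationScenario.null())
    w = t.demographics.set_index("person_id")["weight"]
    fit = fit_usual_intake(days, w, value_col="food_fa_ug")
    est = percent_above(fit, 1000.0)
    oracle = 100.0 * (1.0 - norm.cdf((np.log(1000.0) - 6.5) / 0.4))
    assert est.percent_above == pytest.approx(oracle, abs=1.5)


def test_symmetric_distribution_at_cutpoint_gives_about_half():
    rng = np.random.default_rng(3)
    vals = {f"P{i}": [v, v] for i, v in enumerate(500.0 + rng.normal(0, 40, 400))}
    days = _person_days(vals)
    fit = fit_usual_intake(days, _weights(list(vals)), lam_grid=(1.0,))
    est = percent_above(fit, 500.0)
    assert est.percent_above == pytest.approx(50.0, abs=6.0)


def test_tail_guard_flags_thin_tails_only():
    vals = {f"P{i}": [100.0, 100.0] for i in range(50)}
    vals["BIG"] = [5000.0, 5000.0]
    days = _person_days(vals)
    fit = fit_usual_intake(days, _weights(list(vals)))
    thin = percent_above(fit, 1000.0)
    assert thin.n_above_unweighted == 1 and thin.not_estimable
    empty = percent_above(fit, 10_000.0)
    assert empty.percent_above == 0.0 and not empty.not_estimable


def test_update_intakes_shared_components_are_scenario_monotone(small_survey):
    days_cur = apply_scenario(small_survey.recall, FortificationScenario.null())
    days_mod = apply_scenario(small_survey.recall, FortificationScenario(700.0))
    daily = pd.Series(0.0, index=small_survey.demographics["person_id"])
    w = small_survey.demographics.set_index("person_id")["weight"]
    days_cur["total_fa_ug"] = days_cur["food_fa_ug"]
    days_mod["total_fa_ug"] = days_mod["food_fa_ug"] + days_mod["added_fa_ug"]
    fit_cur = fit_usual_intake(days_cur, w)
    fit_mod = update_intakes(fit_cur, days_mod, w, reestimate_variances=False)
    merged = fit_cur.person_table.merge(
        fit_mod.person_table, on="person_id", suffixes=("_cur", "_mod")
    )
    assert (merged["usual_ug_mod"] >= merged["usual_ug_cur"] - 1e-9).all()
    for c in (200.0, 500.0, 1000.0, 2000.0):
        assert (
            percent_above(fit_mod, c).percent_above
            >= percent_above(fit_cur, c).percent_above
        )
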