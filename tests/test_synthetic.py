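"""Synthetic survey generator: determinism, calibration, replicate weights."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from masafort import (
    ConfigurationError,
    GeneratorConfig,
    generate_replicate_weights,
    generate_survey,
)


def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def test_same_seed_gives_byte_identical_tables():
    a = generate_survey(GeneratorConfig(n_persons=300, seed=9))
    b = generate_survey(GeneratorConfig(n_persons=300, seed=9))
    for name in ("demographics", "recall", "supplements"):
        assert _table_hash(getattr(a, name)) == _table_hash(getattr(b, name))
    c = generate_survey(GeneratorConfig(n_persons=300, seed=10))
    assert _table_hash(a.demographics) != _table_hash(c.demographics)


def test_frac_one_day_zero_means_two_days_everywhere():
    t = generate_survey(GeneratorConfig(n_persons=200, seed=1, frac_one_day=0.0))
    days = t.recall.groupby("person_id")["day_index"].nunique()
    assert (days == 2).all()


def test_one_day_fraction_lands_near_target():
    t = generate_survey(GeneratorConfig(n_persons=2000, seed=2, frac_one_day=0.25))
    days = t.recall.groupby("person_id")["day_index"].nunique()
    frac = (days == 1).mean()
    se = np.sqrt(0.25 * 0.75 / 2000)
    assert abs(frac - 0.25) < 3 * se
    # one-day persons are exactly the 2001-2002 cycle
    demo = t.demographics.set_index("person_id")
    one_day_ids = days[days == 1].index
    assert (demo.loc[one_day_ids, "cycle"] == "2001-2002").all()
    assert demo.loc[one_day_ids, "recall_quality_ok_day2"].isna().all()


def test_degenerate_within_variance_gives_equal_day_totals():
    t = generate_survey(
        GeneratorConfig(
            n_persons=100, seed=4, sigma_within=1e-9, frac_one_day=0.0,
            weekend_bump=0.0, telephone_effect=0.0, n_replicates=10,
        )
    )
    totals = t.recall.groupby(["person_id", "day_index"])["folic_acid_ug"].sum().unstack()
    assert np.allclose(totals[1], totals[2], rtol=1e-6)


def test_supplement_user_fraction_binomial():
    cfg = GeneratorConfig(n_persons=5000, seed=1, supplement_user_prob=0.34,
                          implausible_supplement_prob=0.0)
    t = generate_survey(cfg)
    users = t.supplements["person_id"].nunique()
    se = np.sqrt(0.34 * 0.66 / 5000)
    assert abs(users / 5000 - 0.34) < 3 * se


def test_generator_rejects_bad_fields():
    with pytest.raises(ConfigurationError, match="frac_one_day"):
        generate_survey(GeneratorConfig(n_persons=10, frac_one_day=1.5))
    with pytest.raises(ConfigurationError, match="sigma_between"):
        generate_survey(GeneratorConfig(n_persons=10, sigma_between=-1.0))
    with pytest.raises(ConfigurationError, match="n_replicates"):
        generate_survey(GeneratorConfig(n_persons=10, n_replicates=1))


def test_replicate_weights_zero_one_group_and_conserve_total():
    w = np.ones(4)
    rep = generate_replicate_weights(w, 2, seed=0)
    assert rep.shape == (4, 2)
    for r in range(2):
        col = rep[:, r]
        assert (col == 0).sum() == 2
        assert col[col > 0] == pytest.approx(2.0)
        assert col.sum() == pytest.approx(4.0)


def test_replicate_weights_conserve_any_total():
    rng = np.random.default_rng(7)
    w = rng.lognormal(0, 1, size=137)
    rep = generate_replicate_weights(w, 23, seed=1)
    assert np.allclose(rep.sum(axis=0), w.sum())
    # every person is dropped in exactly one replicate
    assert ((rep == 0).sum(axis=1) == 1).all()


def test_replicate_weights_more_groups_than_persons_errors():
    with pytest.raises(ConfigurationError):
        generate_replicate_weights(np.ones(3), 5, seed=0)


def test_replicate_means_average_to_full_sample_mean():
    """Jackknife consistency: replicate means hug the full-sample weighted mean."""
    rng = np.random.default_rng(11)
    n = 4000
    x = rng.normal(10.0, 2.0, size=n)
    w = rng.lognormal(0, 0.3, size=n)
    rep = generate_replicate_weights(w, 122, seed=2)
    full = np.average(x, weights=w)
    rep_means = (x @ rep) / rep.sum(axis=0)
    assert np.mean(rep_means) == pytest.approx(full, rel=1e-3)


def test_log_scale_variances_match_config_within_3se():
    cfg = GeneratorConfig(n_persons=5000, seed=6, frac_one_day=0.0,
                          weekend_bump=0.0, telephone_effect=0.0)
    t = generate_survey(cfg)
    totals = t.recall.groupby(["person_id", "day_index"])["folic_acid_ug"].sum().unstack()
    z1, z2 = np.log(totals[1]), np.log(totals[2])
    s2w_hat = float(np.mean((z1 - z2) ** 2) / 2)
    means = (z1 + z2) / 2
    s2b_hat = float(np.var(means, ddof=1) - s2w_hat / 2)
    n = len(totals)
    s2w, s2b = cfg.sigma_within**2, cfg.sigma_between**2
    assert abs(s2w_hat - s2w) < 3 * s2w * np.sqrt(2 / n)
    assert abs(s2b_hat - s2b) < 3 * np.sqrt(2 / n) * (s2b + s2w / 2)


def test_truth_fractions_match_monte_carlo_integration():
    """Generated-truth exceedance agrees with direct MC integration of the
    generating distributions (independent oracle) within 0.5 points."""
    cfg = GeneratorConfig(n_persons=50_000, seed=8)
    t = generate_survey(cfg)
    rng = np.random.default_rng(123456)
    m = 400_000
    b = cfg.mu_log_food_fa + cfg.sigma_between * rng.normal(size=m)
    food = np.exp(b + 0.5 * cfg.sigma_within**2)
    user = rng.random(m) < cfg.supplement_user_prob
    doses = np.array(list(cfg.supplement_dose_dist))
    dose = rng.choice(doses, size=m, p=list(cfg.supplement_dose_dist.values()))
    days = np.where(rng.random(m) < cfg.daily_use_prob, 30, rng.integers(1, 30, size=m))
    supp = np.where(user, dose * days / 30.0, 0.0)
    race_levels = list(cfg.race_probs)
    race = rng.choice(race_levels, size=m, p=list(cfg.race_probs.values()))
    p_masa = np.array([cfg.corn_masa_consumer_prob_by_stratum[r] for r in race])
    masa = rng.random(m) < p_masa
    meanlog, sdlog = cfg.nonwholegrain_g_dist
    grams = np.where(masa, rng.lognormal(meanlog, sdlog, size=m), 0.0)
    for cut, frac in t.truth.frac_above.items():
        mc_cur = np.mean(food + supp > cut)
        mc_fort = np.mean(food + supp + grams * cfg.truth_fortification_level / 100 > cut)
        assert abs(frac["current"] - mc_cur) < 0.005, cut
        assert abs(frac["fortified"] - mc_fort) < 0.005, cut
        assert frac["fortified"] >= frac["current"]


def test_truth_fraction_subsets_and_scenario_levels(small_survey):
    truth = small_survey.truth
    ids = truth.persons["person_id"].iloc[:100]
    f0 = truth.fraction_above(1000.0, 0.0, person_ids=ids)
    f1 = truth.fraction_above(1000.0, 700.0, person_ids=ids)
    assert 0.0 <= f0 <= f1 <= 1.0
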