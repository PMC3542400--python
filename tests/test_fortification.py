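"""Fortification arithmetic, scenario application and consumer flagging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from masafort import (
    DomainError,
    FortificationScenario,
    apply_scenario,
    compute_added_folic_acid,
    flag_corn_masa_consumers,
    load_packaged_food_codes,
)

MASA_CODE = sorted(load_packaged_food_codes())[0]


def _recall_rows(rows):
    base = {
        "person_id": "P1",
        "day_index": 1,
        "food_code": "99999999",
        "amount_g": 100.0,
        "folic_acid_ug": 0.0,
        "nonwholegrain_g": 0.0,
        "day_of_week": 3,
        "interview_mode": "in_person",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


@pytest.mark.parametrize(
    "grams,level,expected",
    [
        (32.0, 140.0, 44.8),  # the worked example: 32 g of non-wholegrain
        (0.0, 140.0, 0.0),
        (100.0, 140.0, 140.0),  # definition of the fortificant level
    ],
)
def test_added_folic_acid_values(grams, level, expected):
    assert compute_added_folic_acid(grams, level) == pytest.approx(expected, abs=1e-12)


def test_added_folic_acid_rejects_negative_inputs():
    with pytest.raises(DomainError):
        compute_added_folic_acid(-1.0, 140.0)
    with pytest.raises(DomainError):
        compute_added_folic_acid(10.0, -5.0)


@given(
    grams=st.floats(min_value=0, max_value=1e4, allow_nan=False),
    level=st.floats(min_value=0, max_value=1e3, allow_nan=False),
)
@settings(max_examples=100, deadline=None)
def test_added_folic_acid_is_linear_in_level(grams, level):
    """Doubling the fortificant level doubles the added folic acid."""
    one = compute_added_folic_acid(grams, level)
    two = compute_added_folic_acid(grams, 2 * level)
    assert two == pytest.approx(2 * one, rel=1e-12, abs=1e-12)
    assert one == pytest.approx(grams * level / 100.0, rel=1e-12, abs=1e-12)


def test_apply_scenario_matched_row_gets_worked_example_amount(scenario):
    recall = _recall_rows(
        [
            {"food_code": MASA_CODE, "nonwholegrain_g": 32.0, "amount_g": 50.0},
            {"folic_acid_ug": 120.0},
        ]
    )
    out = apply_scenario(recall, scenario)
    assert len(out) == 1
    assert out.loc[0, "added_fa_ug"] == pytest.approx(44.8)
    assert out.loc[0, "food_fa_ug"] == pytest.approx(120.0)


def test_apply_scenario_sums_matched_rows():
    scen = FortificationScenario(level_ug_per_100g=140.0, corn_masa_food_codes={MASA_CODE})
    recall = _recall_rows(
        [
            {"food_code": MASA_CODE, "nonwholegrain_g": 10.0, "amount_g": 20.0},
            {"food_code": MASA_CODE, "nonwholegrain_g": 20.0, "amount_g": 40.0},
        ]
    )
    out = apply_scenario(recall, scen)
    assert out.loc[0, "added_fa_ug"] == pytest.approx(42.0)  # 14.0 + 28.0


def test_null_scenario_adds_nothing_bit_exactly(small_survey):
    out = apply_scenario(small_survey.recall, FortificationScenario.null())
    assert (out["added_fa_ug"] == 0.0).all()
    zero_level = apply_scenario(
        small_survey.recall, FortificationScenario(level_ug_per_100g=0.0)
    )
    pd.testing.assert_frame_equal(out, zero_level)


def test_scenario_monotone_in_level(small_survey, scenario):
    lo = apply_scenario(small_survey.recall, scenario)
    hi = apply_scenario(
        small_survey.recall, FortificationScenario(level_ug_per_100g=280.0)
    )
    assert (hi["added_fa_ug"] >= lo["added_fa_ug"]).all()
    assert np.allclose(hi["added_fa_ug"], 2 * lo["added_fa_ug"])
    # equality with the current scenario exactly where no matched food was eaten
    untouched = lo["added_fa_ug"] == 0.0
    assert (lo.loc[untouched, "food_fa_ug"] == hi.loc[untouched, "food_fa_ug"]).all()


def test_apply_scenario_rejects_unknown_day_index(scenario):
    recall = _recall_rows([{"day_index": 3}])
    with pytest.raises(Exception, match="day_index"):
        apply_scenario(recall, scenario)


def test_consumer_flag_day2_only_counts(scenario):
    recall = _recall_rows(
        [
            {"person_id": "A", "day_index": 2, "food_code": MASA_CODE},
            {"person_id": "B", "day_index": 1},
            {"person_id": "B", "day_index": 2},
        ]
    )
    flag = flag_corn_masa_consumers(recall, scenario)
    assert bool(flag["A"]) is True  # matched food on either day counts
    assert bool(flag["B"]) is False


def test_consumer_flag_matches_brute_force_recount(small_survey, scenario):
    flag = flag_corn_masa_consumers(small_survey.recall, scenario)
    codes = scenario.corn_masa_food_codes
    recall = small_survey.recall
    expected = {
        pid: bool(grp["food_code"].astype(str).isin(codes).any())
        for pid, grp in recall.groupby("person_id")
    }
    assert flag.to_dict() == expected
    # weighted consumer fraction equals a direct weighted recount
    demo = small_survey.demographics.set_index("person_id")
    w = demo["weight"].reindex(flag.index)
    direct = (w * pd.Series(expected).reindex(flag.index)).sum() / w.sum()
    assert np.average(flag.to_numpy(), weights=w.to_numpy()) == pytest.approx(direct)


def test_packaged_food_list_size():
    codes = load_packaged_food_codes()
    assert len(codes) == 103
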