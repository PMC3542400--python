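"""Supplement averaging and the analytic exclusion cascade.

Converts 30-day supplement reports into average daily supplemental folic
acid, then applies the exclusion cascade (pregnancy, recall quality,
missing supplement information, implausible supplemental intake >= 93 mg)
to a synthetic survey and prints the ledger.
"""

import pandas as pd

from masafort import (
    GeneratorConfig,
    apply_exclusions,
    average_daily_supplement_fa,
    generate_survey,
    ul_for_age,
)

reports = pd.DataFrame(
    {
        "person_id": ["A", "A", "B"],
        "fa_per_serving_ug": [400.0, 1000.0, 400.0],
        "days_taken_past30": [30, 3, 15],
        "servings_per_day": [1.0, 1.0, 1.0],
    }
)
daily = average_daily_supplement_fa(reports)
print("Average daily supplemental folic acid (µg/day):")
print(daily.to_string())
print("  person A: 400×30/30 + 1000×3/30 = 500; person B: 400×15/30 = 200\n")

tables = generate_survey(GeneratorConfig(n_persons=4000, seed=1))
supp = average_daily_supplement_fa(tables.supplements)
cohort, ledger = apply_exclusions(tables.demographics, supp)
print(ledger)

print("\nAge-specific UL cut-points (µg/day):")
for age in (2, 6, 11, 16, 30):
    print(f"  age {age:>2}: {ul_for_age(age):.0f}")
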