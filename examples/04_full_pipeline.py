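"""The full scenario comparison: current vs fortified corn masa flour.

Runs the end-to-end pipeline on a synthetic survey and prints the adult
UL-exceedance table (total population panel): the weighted % of usual
total folic-acid intakes above 1,000 µg/day under current intake and under
fortification at 140 µg/100 g, with jackknife 95% CIs and a paired t-test
of the difference.  Equivalent to: `masafort run --out <dir>`.
"""

import logging

from masafort import GeneratorConfig, RunConfig, run_pipeline

logging.disable(logging.WARNING)

bundle = run_pipeline(
    RunConfig(generator=GeneratorConfig(n_persons=4000), seed=2026)
)

adult = bundle.adult_exceedance
rows = adult[(adult.panel == "total") & (adult.axis.isin(["all", "age_group"]))]
print("Adults: % with usual total folic acid >= 1,000 µg/day")
print(f"{'group':>10} {'stratum':>8} {'n':>6} {'current (95% CI)':>22} {'modeled (95% CI)':>22} {'p':>6}")
for _, r in rows.iterrows():
    cur = f"{r.current_pct:5.2f} ({r.current_lo:.2f}, {r.current_hi:.2f})"
    mod = f"{r.modeled_pct:5.2f} ({r.modeled_lo:.2f}, {r.modeled_hi:.2f})"
    print(f"{r.supp_group:>10} {r.stratum:>8} {r.n_unweighted:>6} {cur:>22} {mod:>22} {r.p:6.3f}")

print(
    "\nModeled exceedance exceeds current by construction, but the increases"
    " are fractions of a point; supplement users exceed the UL an order of"
    " magnitude more often than non-users — supplement use, not fortification,"
    " drives UL exceedance. Generator truth (whole population): "
    f"current {100*bundle.truth_frac_above[1000.0]['current']:.2f}%, "
    f"fortified {100*bundle.truth_frac_above[1000.0]['fortified']:.2f}%."
)
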