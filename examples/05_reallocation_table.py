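"""Isotemporal substitution: the full reallocation table and figure.

For every ordered behavior pair and shift of -60..+60 min (15-min steps),
estimates the expected change in 6-month %TWL of moving that time at the
cohort's compositional mean, with 95% t-intervals. Shifts that would
exhaust the displaced behavior (e.g. 45 min out of a ~40-min MVPA mean)
are infeasible and rendered as dashes.
"""

from timecoda import (
    CohortSimConfig,
    build_reallocation_table,
    fit_coda_model,
    format_reallocation_table,
    plot_reallocation_grid,
    reference_point,
    simulate_cohort,
    true_reallocation_effect,
)

cfg = CohortSimConfig(n_participants=45, seed=7)
cohort = simulate_cohort(cfg)
res = fit_coda_model(cohort)
ref, _ = reference_point(cohort)

table = build_reallocation_table(res.fit, ref,
                                 composition_p=res.test.p_value)
print(format_reallocation_table(table))

est = table[(table["from"] == "sb") & (table["to"] == "mvpa")
            & (table["delta_min"] == 15)].iloc[0]
print(f"\nSB -> MVPA, 15 min: estimate {est['estimate_pct_twl']:.2f} "
      f"[{est['ci_low']:.2f}, {est['ci_high']:.2f}] %TWL; generator truth "
      f"{true_reallocation_effect(cfg, 'sb', 'mvpa', 15):.2f}")
path = plot_reallocation_grid(table, "reallocation_grid.png")
print("figure written to", path)
# Positive estimates mean greater expected weight loss after surgery when
# pre-surgery time shifts into the destination behavior. At n=45 a single
# cohort's estimate is noisy, but its 95% CI covers the generator's truth
# at the calibrated rate (see the coverage checks in the test suite).
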