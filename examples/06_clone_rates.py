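"""Clone proliferation rates: ln(N)/t with larvae as the experimental unit.

Simulates a MARCM-style experiment (8-10 larvae per genotype, 5-30 clones
per disc, ages ~48 h) in which an insulin-receptor mutation slows
proliferation in the wing disc but not the genital disc, then estimates
disc x genotype rates with the two-stage larva-mean estimator and runs
larva-level permutation contrasts plus a cell-size summary.
"""

import math

from allomplast import (
    CloneSimParams,
    cell_size_summary,
    estimate_rates,
    pairwise_rate_comparison,
    simulate_clones,
)

wt = math.log(64.0) / 48.0  # six doublings in 48 h
params = CloneSimParams(
    rates={
        ("wing", "wild-type"): wt,
        ("wing", "InrE19"): 0.075,
        ("genital", "wild-type"): wt,
        ("genital", "InrE19"): wt,
    },
    cell_area_means={"wild-type": 10.0, "InrE19": 9.0},
    seed=8,
)
clones = simulate_clones(params)

print("disc x genotype proliferation rates (ln cells / h):")
for est in estimate_rates(clones):
    print(
        f"  {est.disc_type:8s} {est.genotype:10s} {est.mean_rate:.4f} +/- {est.se:.4f}"
        f"  ({est.n_larvae} larvae, {est.n_clones} clones)"
    )

table = pairwise_rate_comparison(
    clones,
    [
        (("wing", "wild-type"), ("wing", "InrE19")),
        (("genital", "wild-type"), ("genital", "InrE19")),
    ],
    n_perm=10_000,
    seed=9,
)
print("\nlarva-level permutation contrasts (Holm-adjusted):")
for _, row in table.iterrows():
    print(
        f"  {row.disc_a}:{row.genotype_a} vs {row.disc_b}:{row.genotype_b}"
        f"  diff = {row.rate_diff:+.4f}/h, p = {row.p_holm:.4g}"
    )

areas = cell_size_summary(clones, "wild-type", seed=10)
mut = areas[areas["genotype"] == "InrE19"]
print("\ncell-size reductions vs wild-type:")
for _, row in mut.iterrows():
    print(
        f"  {row.disc_type:8s} {100 * row.prop_change_vs_control:4.1f}% "
        f"(95% CI {100 * row.ci_lower:.1f}-{100 * row.ci_upper:.1f}%)"
    )
print(
    "\nThe mutation slows wing-disc clones but not genital-disc clones,"
    "\nwhile shrinking cells ~10% in both — organ-specific growth control."
)
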