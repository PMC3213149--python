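"""Allometric coefficients: how plastic is each organ relative to body size?

Simulates a nutrition-variation experiment with three organs — wing and
maxillary palp scaling proportionally with body size (slope ~1) and
genitalia buffered against nutrition (slope ~0.55) — then fits the SMA
slope of log organ size on log body size for each organ and tests all
pairwise slope differences.
"""

from allomplast import compare_organ_plasticity, log_transform, simulate_foxo_experiment

dataset = log_transform(simulate_foxo_experiment("organ_panel", n=60, seed=42)["pooled"])
estimates, pairwise = compare_organ_plasticity(
    dataset, ["wing", "palp", "genital"], reference="body"
)

print("Allometric coefficient b (SMA slope of log organ on log body), n = 60:")
for organ, est in estimates.items():
    f = est.fit
    print(f"  {organ:8s} b = {f.slope_b:5.3f}  95% CI [{f.ci_lower:.3f}, {f.ci_upper:.3f}]")
print("\nPairwise common-slope tests (Holm-adjusted):")
for _, row in pairwise.iterrows():
    print(f"  {row.organ_a} vs {row.organ_b}: p = {row.p_holm:.4g}")
print(
    "\nb ~ 1 means the organ tracks body size proportionally; the genital's"
    "\nshallow slope (CI below 1) is reduced nutritional plasticity."
)
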