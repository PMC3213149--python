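# Methods

This note documents the statistical models the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Standardized major axis (SMA)

All scaling relationships are fitted on log-transformed sizes by the
standardized major axis, the model-II estimator appropriate when both
variables carry biological and measurement error (ordinary least squares
would attenuate every slope toward zero).  For points (xᵢ, yᵢ):

- slope  b = sign(r) · s_y / s_x, intercept  c = ȳ − b·x̄;
- confidence interval by the correlation-based construction
  B = F(1−α; 1, n−2)·(1−r²)/(n−2),  CI = b·(√(B+1) ∓ √B).

The slope is invariant to the log base (natural log is the default) and to
multiplicative rescaling of raw sizes; only the intercept moves.  Exactly
zero correlation is treated as an error rather than a silent sign choice:
the SMA magnitude is still defined there but its sign is not.  The fit is
validated against a brute-force minimizer of the geometric SMA loss (the
summed areas of the right triangles between each point and the line),
which the closed form must match to 1e-6.

### Common-slope test

Homogeneity of SMA slopes across g groups uses the residual-vs-fitted-axis
correlation form of the likelihood-ratio statistic: at a candidate common
slope b the scores y − b·x and y + b·x are uncorrelated within a group iff
b is that group's SMA slope, so

T(b) = −Σᵢ (nᵢ − 5/2) · log(1 − rᵢ(b)²)

is minimized over b (bounded scalar minimization, inner tolerance 1e-10 on
the slope via xatol 1e-12) and min T is referred to χ²(g−1).  The
(nᵢ − 5/2) weight is the standard small-sample adjustment; measured size
at α = 0.05 over 2000 null simulations (two groups of 50) is ≈ 0.04–0.05,
inside the binomial 99% band.  A permutation variant — group labels
re-dealt over group-centered points, statistic recomputed, add-one
p-value — is provided as an assumption-light internal cross-check; the
two agree in decision on clearly separated slopes.

## Plasticity analyses

- **Allometric coefficient**: SMA fit of log organ on log reference
  (body by default), after pairwise deletion of missing organ values
  (dissection loss is routine and assumed uninformative).
- **Organ comparisons**: all pairwise common-slope tests,
  Holm-adjusted (a reusable pipeline should control family-wise error;
  raw p-values are also emitted).  Results are order-invariant.
- **Effect sizes**: proportional reduction 1 − perturbed/control of raw
  mean organ size, with a percentile bootstrap (individuals resampled
  within group, 2000 resamples, seed mandatory).  Raw-scale ratios match
  the "reduced by ~30%" idiom; log-scale differences are used inside the
  interaction test below for variance stabilization.
- **Differential effect (organ × treatment interaction)**: the statistic
  is the between-organ difference of control-minus-perturbed log-mean
  sizes; the null permutes treatment labels over individuals, preserving
  each individual's organ pairing.  Verified against exhaustive
  enumeration of all C(6,3) labelings on a six-fly toy.
- **Quadratic trend** (expression vs plasticity): OLS on (1, x, x²) with a
  pointwise 95% band and the fitted extremum −a₁/(2a₂); replaced-by-linear
  nesting is tested (quadratic RSS ≤ linear RSS).

Tukey-style mixed-ANOVA contrasts of the original analyses are deliberately
replaced by these permutation/bootstrap analogues: the raw ANOVA layout is
not recoverable from summary data, and resampling matches the slope-trend
test's logic while making every assumption explicit.

## Temperature normalization

To plot experimental scaling relationships from different rearing
temperatures against one common control relationship, each non-reference
condition is (1) rigidly translated so the bivariate mean of its fed
("un-starved") control flies equals the reference condition's fed-control
mean, and (2) rigidly rotated about that anchor until the control SMA
slope equals the reference control slope.  Experimental rows undergo the
identical motions, so all within-condition geometry (pairwise distances,
offsets from the anchor) is preserved to 1e-9.

Numerical choices: the transform acts in log-size coordinates (rotation is
only angle-consistent in a fixed frame); the angle is
arctan(target) − arctan(current); and because a rigid rotation moves a
noisy cloud's SMA slope exactly to the target only in the collinear limit,
the implementation refits after rotating and runs a fixed-point iteration
on the angle (typically < 10 steps) until |slope − target| ≤ 1e-9, with
the iteration count recorded on the returned transform.  Order is
translate-then-rotate; the rotation anchor is the post-translation control
mean.  A second normalization pass yields identity transforms
(idempotence), and the reference condition is returned bit-identical.

## Slope-trend permutation test

For groups indexed by a numeric covariate (rearing temperature), the
observed trend b_O is the OLS coefficient of per-group SMA slope on the
covariate.  Null resampling: center each group at its bivariate mean,
pool, deal the pooled points back into groups of the original sizes
without replacement (covariate values stay attached to groups, not
points), and recompute the trend, 1000 times by default.  The lower-tail
p is the raw proportion of b_A ≤ b_O, ties counted; the add-one estimator
(k+1)/(n_perm+1) is reported alongside because it is finite-sample valid
and can never return exactly zero (at n_perm = 200 its exact level at
α = 0.05 is 10/201 ≈ 0.0498, whereas the raw proportion's is 11/201).
Permutations that produce a degenerate group (zero variance on an axis or
exactly zero correlation, where the SMA slope is undefined) are redrawn
and the redraw count reported; at realistic group sizes redraws are
essentially never triggered.  Two-point groups are admitted (with a
warning) so that tiny enumeration oracles can be run; fit_sma proper
requires n ≥ 3.

## Clone proliferation statistics

Per-clone rate: ln(N)/t per hour (natural log; base 2 — doublings per
hour — is a constant rescaling and available via the `base` argument).
Larvae are the independent units, so estimation is two-stage: clone rates
are averaged per larva per disc, then unweighted across larvae within each
disc × genotype cell.  The between-larva variance component τ² is
estimated by one-way random-effects method of moments for unbalanced clone
counts k per larva: τ̂² = max(0, var(larva means) − σ̂²_w·mean(1/k)), with
σ̂²_w the pooled within-larva variance.  The reported standard error is
the model-based one for the unweighted larva-mean estimator,
√(τ̂²/n + σ̂²_w·mean(1/k)/n) — the quantity a mixed model with larva as a
random effect reports, and better calibrated at 8–10 larvae than
sd(larva means)/√n because its within-larva part carries clone-level
degrees of freedom.  Pairwise contrasts permute larva means between two
design cells (add-one p, Holm across the family); cell-size summaries
aggregate clone mean areas per larva and bootstrap the proportional change
versus the control genotype.

## Synthetic-data generators

The generators define the conditions under which the pipeline is
validated; their defaults are the study's design constants wherever those
are known, and explicit package choices elsewhere.

**Allometry.**  Latent log body size z ~ N(μ_treatment, 0.2²) emulates the
starve-at-different-sizes design that produces a wide, nutrition-driven
size range.  Observed log body = z + e_x with sd(e_x) = 0.06; each organ's
observed log size = c + b_eff·z + e_y with sd(e_y) = |b_eff|·sd(e_x).
Loading noise on both axes in the ratio b² is the identification choice
that makes the generating slope equal the SMA estimand (verified at
n = 2000, |bias| < 0.01); it mirrors the symmetric error roles SMA itself
assumes.  b_eff adds genotype slope offsets and a linear per-°C
temperature term.  Default slopes: genitalia 0.55 (controls) and 0.93
(growth-inhibitor mutants), wing and palp 1.0; default temperature trend
−0.0105/°C — magnitudes taken from the study the scenarios emulate.  The
noise scales (body-size spread 0.2, axis noise 0.06 on the log scale) are
package defaults chosen to give single-experiment interval widths
comparable to the published ones (control CI spanning roughly 0.46–0.61
at n = 60); real measurement-error magnitudes are not published.

**Clones.**  Per larva a rate offset u ~ N(0, 0.004²); per clone
r = group rate + u + N(0, 0.02²), age t ~ Uniform(44, 52) h, and
N = max(1, round(e^{rt})) — an observed clone contains at least its
founder.  Design constants follow the study: 8–10 larvae per genotype,
5–30 clones per disc, ages around 48 h; wild-type default rate
ln(64)/48 ≈ 0.0866 h⁻¹ (six doublings in ~48 h).  Larva-to-larva
variation is set smaller than clone-to-clone variation (≈5% vs ≈23%
coefficient of variation on the rate), reflecting that clone-size spread
dominates MARCM data; these two sds are package defaults, not published
values.

**What the generators do not emulate**: shared-body-size correlation
between organs beyond the latent z (no organ-organ residual correlation),
measurement-unit heterogeneity (areas vs lengths), non-normal size
distributions, clone death/fusion, or spatial structure within discs.
Passing tests therefore demonstrate correctness of the estimators and
tests under the stated model, not robustness to every feature of real
measurements.

## Problem sizes and determinism

Every stochastic routine requires an explicit seed (NumPy PCG64) and is
reproducible bit-for-bit under it.  The validation suite uses the
Monte-Carlo sizes its claims need: 100 datasets for the SMA loss oracle,
1000 replicates for CI coverage, 2000 null simulations for test
calibration, 200 replicates for power at the study's effect sizes, 500
runs for permutation-p uniformity, and 500 simulated clone experiments for
recovery coverage.

## Known limitations

- The common-slope statistic's χ² reference is asymptotic; at very small
  group sizes (< ~15) prefer the permutation method.
- The correlation-based SMA CI assumes approximate bivariate normality on
  the log scale.
- The raw-proportion permutation p can be exactly zero; use the add-one
  value when a strictly positive p is required.
- Holm adjustment controls family-wise error only within the requested
  family of contrasts.
- The normalization's fixed-point rotation matches the control slope, not
  the full control distribution; conditions whose control clouds differ in
  shape (not just slope and mean) remain distinguishable after
  normalization, by design.
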