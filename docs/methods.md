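# Methods

This note documents the models implemented in `lipotherm`, the numerical
choices behind them, what the synthetic cohorts emulate, and the limits of
what the tests demonstrate.

## Retention models

**Isocratic lipophilicity.** Retention factors k = (t_r − t_0)/t_0 are
assumed log-linear in the organic-modifier volume fraction φ
(Soczewiński–Wachtmeister / linear solvent strength):

    log10 k = log k_w + S·φ,   S < 0 in reversed phase.

`S` is stored as the raw fitted slope, so it is negative; sources that
write the model with an explicit minus sign report the same negative
numbers. `log k_w` (retention extrapolated to pure water) always lies
outside the measured φ range, so every result carries a `range_warning`
rather than being refused — extrapolated lipophilicity indices are standard
practice, but the flag keeps the caveat attached to the number. φ₀, the
composition at which k = 1, is the root of the fitted line,
φ₀ = −log k_w / S, which satisfies the defining interpolation exactly.
Logarithms are decadic here; conversions to natural logs elsewhere are
explicit and local. φ is always a fraction in [0, 1]; percentage inputs are
declared in the I/O dialect and converted on read.

**Temperature dependence.** At fixed φ, ln k is regressed on 1/T (van't
Hoff):

    ln k = −ΔH°/(R T) + ΔS°/R + ln Φ,

with R = 8.314 J mol⁻¹ K⁻¹ (full precision; rounding R to 8.31 changes
nothing at the reported precision). The phase ratio Φ of the column is
unknown and no attempt is made to estimate it: the intercept-derived
entropy is reported as ΔS°* = ΔS° + R ln Φ and labelled biased everywhere.
Pairwise ΔΔS°* between compounds on the same column cancels the bias
exactly; the test suite verifies this by scaling all k by a constant.
ΔG° = ΔH° − T·ΔS°* at a reference temperature (default 293.15 K, the
typical 20 °C column thermostat; configurable) carries the same constant
−T·R ln Φ offset and is therefore comparable across solutes, not across
columns. Series require ≥ 4 temperatures spanning ≥ 20 K. A linearity gate
(R² > 0.9, configurable) marks trustworthy fits; failing series — typical
for acetonitrile-rich eluents, where modifier multilayer adsorption and
temperature-dependent phase volume distort the plot — are flagged, and the
Gibbs combination refuses them unless explicitly overridden (it then warns).

**Molecular-difference selectivity.** For a declared pair measured on a
shared (modifier, φ, T) grid, the slope of ln α against 1/T, with
α = k_high/k_low, gives the transfer enthalpy of the pair's molecular
difference, ΔH°d = −R·slope. Because Φ divides out of α, ΔH°d is free of
the phase-ratio bias. On a shared grid, OLS linearity in the response makes
ΔH°d *identically* equal to the difference of the two individually fitted
ΔH° values; this exact identity is the module's core oracle test. The more
retained member is chosen by higher mean ln k over the shared grid (ties
broken lexicographically with a warning), so a reversed declaration is
corrected rather than producing a sign error. The gate is stricter here
(R² > 0.97): high ln α linearity is the operational evidence that both
members access the same stationary-phase volume. Non-linear pairs are
reported with `linear_ok = False`, not dropped. Pairs are user-declared;
inferring which structural moiety differs is out of scope.

## Regression engine

All fits go through one simple-OLS routine (scipy's `linregress` plus
closed-form diagnostics): slope, intercept, R², residual standard error
s_e = √(SS_res/(n−2)), F = (n−2)·R²/(1−R²) (infinite for exact lines), and
95% confidence half-widths from Student t with n−2 df. "±" values in all
summaries are those half-widths, with plain standard errors also carried.
Fits require n ≥ 3 and non-constant x; an exactly flat response is treated
as an exact fit (R² = 1, s_e = 0) rather than 0/0. No weighting or robust
loss: the measurement model throughout is homoscedastic noise on the log
scale. The independent oracle in the tests is a hand-written
normal-equations solve, cross-checked further against statsmodels OLS for
the diagnostic terms.

## Descriptor correlation

The cross-correlation stage reports squared Pearson correlations
("determination coefficients" in the bivariate sense) between derived
parameters (S, log k_w, φ₀ per modifier; ΔH°, ΔG°) and arbitrary numeric
descriptor columns, pairwise-complete with per-cell n; cells with < 3
shared compounds are undefined (NaN), and nothing is imputed. Rank
(Spearman) correlation is available but off by default. No
multiple-testing correction is applied — the output is a screening matrix,
and the JSON carries a note saying so.

## Activity models

ED50 (mg/kg; lower dose = more potent) across a congeneric series is
treated as a two-population mixture; the discrimination boundary defaults
to 350 mg/kg and can be re-estimated as the valley of a Gaussian KDE on
log10-dose between the two largest modes (doses are right-skewed, so the
log scale is the natural one; the valley of well-separated components
lands near their geometric midpoint). Unimodal or tiny samples fall back
to the configured default. The class convention is ED50 < threshold →
"active"; records exactly at the threshold are inactive.

Classification families: elastic-net logistic regression (grid over C and
l1_ratio), random forest (500 trees, small max_features grid), and PLS-DA
(PLS regression on a 0/1 indicator, 0.5 cut, 1–3 components). Regression
families: elastic-net, random forest, PLS. Tuning is repeated 3-fold CV
(10 repeats by default) on a seeded train split whose default proportions
are 9:5, the realistic scale for a 14-compound series; metrics are
accuracy (classification) and RMSE/R²/MAE (regression). Standardization
lives inside the sklearn pipeline, so it is refit on every training fold;
feature selection likewise runs on the training split only. A canary test
demonstrates the leak this prevents: univariate screening performed on the
full table before CV reports far-better-than-chance accuracy on pure
noise, while the in-fold protocol stays at chance. (Leaked
standardization alone is nearly neutral for scale-equivariant pipelines;
screening is the leak with teeth, so that is what the canary uses.)

Variable importance is model-agnostic permutation importance (mean metric
degradation over seeded column shuffles), computed on held-out data for
every feature supplied to the final model. Feature selection offers
recursive elimination (drop the least permutation-important feature,
score every subset size by CV, keep the best) and simulated annealing over
subset space (seeded Metropolis walk, geometric cooling, default 40
iterations, T₀ = 0.02, ratio 0.9), both returning their evaluation trace.
A single-class training fold triggers a bounded reseeded retry before
erroring. With identical seed, config and data, reports are
bit-reproducible.

Exact replication of literature accuracies from unseeded 9/5 splits of
unpublished feature tables is a non-goal; the tests instead verify the
properties that make such numbers meaningful: perfect separation when the
margin is large, chance-level behaviour under label permutation, and
recovery of a planted φ₀-linked signal.

## Synthetic cohorts

The generator produces the joint structure the analysis assumes, with the
ground truth exported for recovery tests. Defaults describe a
14-compound congeneric series measured in methanol (φ 0.15–0.40) and
acetonitrile (φ 0.05–0.30) at 20 °C, with temperature series at φ = 0.15
over 5–45 °C in 5 K steps:

* S(ACN) ~ N(−3.816, 0.55²); S(MeOH) = 0.7682·S(ACN) + 0.086 + ε;
  log k_w = −0.4205·S + 0.454 + ε (MeOH) and −0.3359·S + 0.3145 + ε (ACN),
  with residual sds (0.063, 0.020) chosen so the similarity regressions
  average R² ≈ 0.90 and ≈ 0.99 — the collinearity levels characteristic of
  a single-mechanism congeneric series in the two systems.
* ΔH° is drawn retention-linked (−5 − 8·log10 k_ref kJ/mol + noise in
  MeOH, shallower in ACN), and ΔS°* is anchored so the van't Hoff line
  passes through the isocratic point at (φ_ref, T_ref). That consistency
  anchor makes ΔG°(T_ref) = −R·T_ref·ln k(φ_ref, T_ref) exactly, which
  with the calibrated retention scale puts the methanol-system ΔG° range
  near −8…−5 kJ/mol.
* Four declared pairs (two heteroatom swaps, with and without a methylene
  linker; two methylene homologue pairs) are built as true congeners: the
  more-substituted member's S is lower by a per-pair decrement (split
  symmetrically so cohort means are preserved) and shares its partner's
  deviations from the calibration maps, which fixes the pair's ΔΔG°
  selectivity near 1.3 kJ/mol (heteroatom) and 0.65 kJ/mol (methylene) in
  methanol; its ΔH° is offset by the pair's transfer enthalpy
  (−3.8 / −5.5 kJ/mol heteroatom, −1.7 / −3.3 kJ/mol methylene in MeOH,
  30–40% shallower in ACN).
* Measurement noise, sd 0.01 on log10 k in total, is decomposed into a
  condition-level systematic part (shared by all compounds run under the
  same modifier/φ/T, 99% of the variance) and an independent
  injection-level part (10% of the sd). Retention precision in practice is
  dominated by eluent-batch, flow and thermostat drifts that affect
  co-conditioned runs alike; the systematic part cancels in selectivity
  ratios, which is how well-matched pairs achieve the near-perfect ln α
  linearity the 0.97 gate expects while single-series residuals stay an
  order of magnitude larger.
* Descriptors are affine in ΔG°(MeOH) with noise variance solved to hit a
  target R² in expectation (defaults: polarizability and DFT binding
  energy 0.86, calculated log P 0.5, docking energy 0.3, BBB 0.1).
* ED50 is a lognormal mixture (medians 110 and 620 mg/kg, sigmas 0.30 and
  0.25 — modes either side of the 350 mg/kg boundary) whose class is
  Bernoulli with a logistic link on true φ₀(MeOH) (default scale 60;
  "strong link" simulations use 300).

Retention, descriptor and activity draws come from independently spawned
streams of the master seed, so regenerating descriptors never perturbs the
retention table. Regeneration with the same arguments is byte-identical.

What the cohorts do **not** emulate: curvature of log k–φ at high modifier
content, van't Hoff non-linearity from phase transitions or
temperature-dependent phase ratios (gate-failure behaviour is tested with
explicitly constructed curved series instead), replicate injections,
inter-batch column variability, pressure/compression effects, and real
descriptor covariance structure beyond the single ΔG° link. Passing tests
therefore demonstrate correctness of the estimators under the stated
measurement model, not robustness to every pathology of real
chromatograms.

## Problem sizes and runtime choices

The default test and acceptance workloads use the study-scale cohort
(14 compounds), 500 single-compound replicates for CI-coverage
calibration, 30 replicates for the classifier null, and a 50-compound
cohort for activity recovery — sizes at which every check runs in seconds
on one CPU while keeping binomial/Monte-Carlo error well inside the
asserted bands (500 replicates put the standard error of a 95% coverage
estimate at ~1%).

## Known limitations

* The van't Hoff reference temperature for ΔG° is a convention; results at
  other T_ref follow exactly linearly (slope −ΔS°*), but published tables
  rarely state their choice, so cross-study comparison of ΔG° needs care.
* φ₀ from acetonitrile systems inherits any log k–φ non-linearity;
  the model fits a straight line regardless and reports R².
* With n ≈ 14, held-out metrics from a single 9/5 split have very wide
  sampling error; the repeated-CV numbers are the more stable quantity,
  and both are reported.
* The F statistic is reported with the textbook (n−2) denominator df;
  exact lines report F = ∞ rather than a capped value.
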