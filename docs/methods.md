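# Methods

## Cole model and fitting

The complex impedance of the body over frequency is modelled as
`Z(f) = R∞ + (R0 − R∞)/(1 + (j·f/fc)^(1−α))` with the (f/fc)
parameterization (equivalent to the ωτ form; avoids unit juggling). A
time-delay correction is not part of the core model; the fitting routine is
the single place it would enter if an instrument required it. Reactance is
stored everywhere as the magnitude of the capacitive reactance (−Im Z),
removing the sign-convention ambiguity of instrument exports.

Fitting minimises the summed squared deviation jointly over the real and
imaginary parts with equal weights — the geometric misfit in the Cole plot.
Initialisation is robust on semicircular loci: R0 ← 1.05 × max measured
resistance, R∞ ← 0.95 × min, fc ← frequency of maximal reactance, α ← 0.1,
with bounds 0 ≤ α ≤ 0.95 and positive resistances. `fit_rmse` is the RMS
modulus of the complex residual (Ω); fits with `fit_rmse > 1% of R0` carry a
quality flag, operationalising "poorly fitted" Cole plots. Spectra with
numerically zero reactance or constant resistance raise a
non-identifiability error rather than returning an arbitrary fit.
Triplicates are combined by the parameter-wise median (robust to one
movement-corrupted sweep), reporting the replicate CV of R50.

## Mixture theory

Extracellular water uses the Hanai wire-conductor relation
`V_ECW = k·(H²√W/R0)^(2/3)` with
`k = 1e-3·(1000·Kb²·ρ_ecw²/D_b)^(1/3)` (H cm, W kg, V litres). With
Kb = 4.3, ρ_ecw = 40.5 Ω·cm, D_b = 1.05 kg/L this reproduces the widely
published adult constant k ≈ 0.306 and gives ~4 L for a 15 kg child; the
constant is dimensionally forced once Kb is defined as the dimensionless
whole-body geometry factor.

Intracellular water solves
`(1 + V_I/V_E)^(5/2) = ((R0 + R_I)/R_I)·(1 + K_ρ·V_I/V_E)` with
`R_I = R0·R∞/(R0 − R∞)` and `K_ρ = ρ_ecw/ρ_icw` — the conductivity ratio of
the two aqueous phases. With the reciprocal (resistivity) ratio the equation
keeps a root near V_I/V_E ≈ 1.9 even as R∞ → R0, i.e. predicts intracellular
water when no current crosses the membranes; the conductivity form keeps the
positive root unique, restores the exact limit ICW → 0, and makes predicted
water decrease when the whole Cole locus scales up. The root is found by
bracketed bisection on V_I/V_E ∈ (0, 10) to 1e−12 plus one Newton polish
(residual < 1e−10 relative, guaranteed convergence on the monotone
bracket). The Moissl variant replaces the fixed constants with BMI-adjusted
coefficients (0.188/BMI + 0.2883 for ECW on R0; 5.8758/BMI + 0.4194 for ICW
on R_I).

Monotonicity caveat: raising R0 *alone* shrinks R_I and legitimately raises
predicted ICW for every scheme that uses the intracellular resistance, so
"more resistance ⇒ less water" holds for joint scaling of (R0, R∞), not for
R0 in isolation; the tests assert the joint-scaling form.

Six coefficient schemes are registered (SFB7 default, SFB7 with per-child
Kb, Moissl, Xitron Hydra, Xitron 4000B, 4000B with the Ellis paediatric
adjustment). The instrument vendors do not publish their constants in
citable form: registry entries other than the De Lorenzo adult pair
(40.5/273.9 Ω·cm) and the Moissl coefficients are explicitly flagged
`assumed`, and every constant can be overridden per run. TBW converts to FFM
by age- and sex-band hydration fractions of FFM; the shipped two-entry table
(M 0.767, F 0.762 over 2–6 y) is likewise a working default — supply a
study-specific table for substantive use.

Consequence worth knowing: with the assumed adult resistivity pair, the
conductivity-form ICW is small and the Hanai-family schemes underestimate
FFM by several kg on the synthetic cohort, while the Moissl scheme lands
within a few hundred grams. The scheme *ranking* is a stable property of
the coefficient sets (tested across seeds); the absolute mixture biases are
not calibrated to anything and should not be read as validated physiology —
consistent with the general finding that adult mixture constants transfer
poorly to young children.

## Empirical equations and development pipeline

All prediction equations are exactly affine and evaluated with their
published coefficients; "length" and "standing height" are the same measured
quantity at this age. Ethnicity collapses Chinese/South Asian/Indian to the
Asian indicator, with "Other" defaulting to non-Asian. Out-of-range
covariates warn rather than fail: the equations are documented as valid only
near the development cohort's range (weight 5–40 kg, height 70–130 cm), and
the intercept-only values outside it are meaningless. Fat mass subtracts
predicted FFM from adjusted scale weight (`Wt_adj = 0.41 + 0.99·Wt_scale`),
or from raw scale weight under the Rush convention; negative FM is returned
with a warning, never silently clipped.

Development: the cohort splits into derivation/validation sets by a seeded
RNG stratified by sex, taking round-half-up(fraction × stratum size) per
stratum (0.69–0.70 reproduces the 45/20 split of a 25 M + 40 F cohort). The
split seed is a required, recorded input. Stepwise selection is
bidirectional on AIC — the conventional reading of "bidirectional stepwise"
when the criterion is unstated — starting from the base terms, one add/drop
per step, deterministic given the data. RMSE is the residual standard error
√(SSE/(n−p−1)); standardized coefficients are b_j·SD(x_j)/SD(y). Meal/void
categories enter as ordinal integers 0–3.

## Agreement statistics

Differences are predicted − reference throughout (positive bias =
overestimation). CCC uses Lin's n-denominator moments with the standard
asymptotic Fisher-z variance for its CI. Bland–Altman LOA are bias ±
1.96·SD(differences, n−1); proportional bias is the two-sided t-test on the
OLS slope of differences against pairwise means (the relationship the
Bland–Altman plots display). Passing–Bablok enumerates all pairwise slopes,
drops zero-denominator pairs, excludes slopes equal to −1, and shifts the
median by the count of slopes below −1, with rank-based CIs; the intercept
is median(y − slope·x). TOST runs two one-sided paired t-tests against
±bound and reports the larger p; the equivalence decision is algebraically
identical to the 90% CI of the mean difference lying inside the bounds, and
zero-variance differences are decided exactly. The tabulated `p` column in
the method-comparison output is the proportional-bias p-value.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the *statistical structure* the pipeline needs:
sex/ethnicity mix (25/65 male, 14/65 Asian), sex-specific height
(M 100.3 ± 3.4, F 98.6 ± 3.5 cm) and weight (M 15.7 ± 2.0, F 15.3 ± 1.7 kg)
with within-sex weight–height correlation 0.6, and DXA FFM means of
12.0 (M) / 11.1 (F) kg. Latent FFM is affine in weight, sex and ethnicity
plus a physiological residual of 1.06 kg; the weight slope (0.15 kg/kg
conditional on sex) and residual were chosen once so the pooled FFM SD lands
at ≈ 1.2 kg. The impedance index is then *defined* by inverting the final
equation at the latent FFM, which makes that equation the exact ground truth
and fixes R50 = H²/index; R0 = 1.090·R50 and R∞ = 0.828·R50 use the
cohort-level ratio estimates, and fc follows by solving
Re Z(50 kHz) = R50 — a single cohort-wide constant (~75.9 kHz), a direct
consequence of sex-invariant ratios and fixed α = 0.10. DXA FFM adds
0.39 kg of reference noise; DXA weight follows the adjusted-weight relation
plus 0.05 kg noise; DXA FM closes the mass balance. Draws yielding R50
outside (300, 1500) Ω or DXA FM below 0.2 kg are resampled (counted and
capped) — preschool FM% is ~25 ± 3.5, so near-zero FM is out-of-population.

Replicate noise is a common per-replicate scale factor with CV 0.17% plus
0.05% per-point noise. The common factor is deliberate: purely independent
per-point noise would average out over 256 frequencies and shrink the
replicate CV of fitted R50 by an order of magnitude, contradicting the
instrument-precision figure the CV emulates.

What passing tests do and do not show: because the impedance index absorbs
the full physiological residual by construction, the index is a nearly
perfect FFM predictor here (up to DXA noise) and weight alone explains very
little — unlike a real cohort, where weight alone explains ~73% of FFM
variance and the index carries partially redundant information. The refit
R², RMSE, validation MAPE and published-equation biases are therefore
recoverable by construction; the ladder's *lower* rows and any claim about
real children's physiology are not. With the physiological residual fixed
at 1.06 kg and the sex means calibrated, the population adjusted R² of the
refit final model cannot fall below ≈ 0.89, so the multi-seed average sits
~1.5 points above the 0.88 it emulates, within the acceptance band; a larger
weight slope would push it out the other side. Per-child RNG streams are
keyed by (seed, child index), so per-child draws are independent of cohort
size and byte-identical across runs.

## Problem sizes

The replication studies use 200 cohorts of 65 children (derivation ≈ 45,
validation ≈ 20) for the refit and published-bias summaries and a single
10,000-child all-male cohort for the calibration mean — sizes at which the
Monte-Carlo standard error of every reported mean is an order of magnitude
below its acceptance tolerance, while the full acceptance script completes
in seconds.

## Known limitations

* Mixture-theory absolute volumes depend on an assumed resistivity pair the
  source instruments do not publish; only scheme ranking is asserted.
* The generator's FFM–weight structure is diagnostic plumbing, not
  physiology (see above); anthropometric ladder rows on synthetic data do
  not match a real cohort's.
* Hydration fractions are band constants, not per-child maturation curves.
* Measurement-side effects (left vs right) and DXA artefacts (movement,
  limb reflection) are out of scope.
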