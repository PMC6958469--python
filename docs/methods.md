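# Methods

This note documents the models, conventions and numerical choices behind
`radiosynergy`, and what the synthetic-data experiments do and do not
demonstrate.

## In vitro: dose–response and combination index

**Normalization.** Raw plate signals are converted to fraction-of-control
viability as `(raw − mean(blank)) / (mean(control) − mean(blank))`. A plate
whose control mean does not exceed its blank mean is rejected as degenerate.

**4PL fit.** Each curve is fitted in log10-dose space with
`v(D) = bottom + (top − bottom) / (1 + (D/ec50)^hill)` by least squares
(scipy `least_squares`, TRF). Three deterministic starts — data-driven
(hill ±1), steep (±3) and shallow (±0.5), with the sign taken from the raw
slope — guard against local minima; the best SSE wins. Dose-zero wells are
excluded from the log-dose fit. Near-constant curves (span < 1e-9) short-
circuit to a flat fit with an explicit status instead of a degenerate
optimization.

**Absolute IC50.** The dose at which *predicted viability = 0.5 of
untreated control* (not 0.5 of the fitted span), inverted in closed form:
`IC50 = ec50 · ((top − 0.5)/(0.5 − bottom))^(1/hill)`. When the fitted
curve never crosses 0.5 the result is undefined with a status that
distinguishes `bottom-above-half` from `top-below-half`. Fraction affected
(fa = 1 − viability) is likewise defined against untreated control; this is
the reading consistent with "absolute IC50" when curves have a nonzero
bottom plateau.

**Median-effect fit.** `log10(fa/fu)` is regressed on `log10 D`
(fa/fu = (D/Dm)^m). Replicates are averaged per concentration first.
Viabilities are clipped into (0.001, 0.999) before the transform; wells
that sit *at* a clip boundary are saturated at the assay's dynamic-range
limit and are excluded from the regression — a boundary-valued point
carries no slope information and regressing it biases Dm (measurably: a
self-combination sham drifts to CI ≈ 0.82 at hill 2 if saturated wells are
kept). At least 3 interior points are required; fewer raises an
insufficient-dynamic-range error. The clip bounds are configurable.

**Fixed-ratio design.** Two agents titrated alone and in nine mixtures
`w_A·C1 + w_B·C2`, w_A = 0.9 … 0.1. Internally the mixture dose axis is
the dimensionless *fraction of the top concentrations*, which avoids mixing
kBq/mL and µM on one axis; decomposition back to native units uses the
design weights and top concentrations. This makes the combination index
exactly invariant under rescaling of either agent's concentration unit.

**Combination index.** CI is evaluated at the 50% effect level by default
(other levels are supported but off by default). For each ratio, the
combined dose reaching the effect level is read off a 4PL fit of the
mixture curve by closed-form inversion — the mixture's absolute iso-effect
dose. The global median-effect regression line is *not* used for this
crossing: on curved combination surfaces (e.g. a Bliss-independent product
of two hill-1 curves) its log-log linearization misplaces the 50% crossing
by 12–26%, whereas the 4PL inversion agrees with a brute-force grid search
of the true surface to ≤1% and leaves the self-combination sham exact at
any hill slope. The mixture's median-effect parameters (Dm, m, r²) are
still computed and reported. The single-agent iso-effect doses come from
their median-effect fits (D = Dm at 50%). The two-term index is

    CI = d_A / D_A,50 + d_B / D_B,50

with classification synergistic (CI < 0.8), additive (0.8 ≤ CI ≤ 1.2,
boundaries inclusive so the classes partition the line), antagonistic
(CI > 1.2). The average CI is the arithmetic mean over evaluable ratios; a
mixture whose fitted curve never reaches the effect level is flagged,
excluded and counted, with a warning surfaced in the result.

Note an intrinsic property, not a bug: a Bliss-independent surface of two
hill-1 agents has Loewe-type CI slightly below 1 (CI = 1 − x·y on the 50%
contour, x and y the normalized component doses). Exact CI = 1 under Bliss
independence would require the three-term "mutually nonexclusive" index;
the two-term index above is the field's standard and the one used here.

**Isobologram.** The two axis intercepts are the single-agent absolute
IC50s from the 4PL fits; each evaluable ratio contributes its (d_A, d_B)
point. Points below the straight line between the intercepts correspond to
CI < 1.

## In vivo: T/C, significance and Bliss calls

**T/C.** Treated-group mean tumor volume divided by vehicle-group mean at a
reference day. The default reference day is the last study day on which
every vehicle animal remains uncensored (configurable). Animals are
censored at the humane endpoint (volume ≥ 1,500 mm³): the triggering
measurement is kept, later ones are excluded from group means, and no
last-observation-carried-forward is applied (carrying forward a terminal
volume would bias group means downward exactly in the fastest-growing
arms).

**Significance.** One-way ANOVA structure across arms on the reference-day
volumes with Tukey-HSD adjusted pairwise p-values (statsmodels); the
vehicle contrasts are reported, significant at 0.05.

**Doubling time.** Per animal, ln(volume) is regressed on day;
Td = ln 2 / slope, undefined with a "no growth" status for non-positive
slopes; the group value is the mean over growing animals.

**Bliss conventions.** The Bliss null `C = A + B − A·B` is a statement
about *effects*. Applied to inhibition (1 − T/C) it is algebraically
identical to multiplying the T/C values: expected T/C = A·B. Applied
literally to T/C it predicts a combination worse than either monotherapy
(A = 0.8, B = 0.5 → 0.9), which contradicts its use as an additivity
reference; the inhibition-scale product is therefore the default and the
literal form is retained behind a flag for comparison. Only the default
reproduces the published call pattern from the shipped T/C table. The
synergy margin is 0.10 in *absolute* T/C units (percentage points), the
only reading consistent with that same pattern; a relative margin is not
offered. Calls: observed < expected − margin → synergistic; observed >
expected + margin → antagonistic; boundaries additive (with a 1e-9
float-tolerance so exact-boundary arithmetic stays additive). Monotherapy
T/C values feeding a call must come from the same study at the same
reference day; `study_bliss_table` makes mixing days structurally
impossible, and `bliss_table` on an external T/C table requires both
monotherapy arms to be present.

**Hematology.** Counts are expressed as fraction of the pre-dose baseline
(samples at day −1/−2 are treated as the day-0 baseline). The nadir is the
series minimum with its day; a series that never drops below baseline is
flagged "no suppression". Recovery is the first post-nadir day at
≥ (1 − tolerance) × baseline, tolerance 0.1 by default; group summaries run
these rules on the per-day group mean.

## Radiometrics

Half-lives: Th-227 = 18.7 d; Ra-223 = 11.43 d (standard nuclide data; the
registry is overridable by config). Internal times are hours. Decay
correction to injection time is `A · 2^(t/T½)`, the exact inverse of
forward decay. %IA/g = decay-corrected activity / injected activity /
sample mass × 100; detector counts are assumed calibrated to Bq upstream
(gamma-peak efficiency math is out of scope). Specific activity is
activity dose / protein dose with unit conversion (300 kBq/kg at
0.14 mg/kg → 2.14 kBq/µg, printed as 2.1). Molar conversion uses
N = A/λ atoms: 22 kBq/mL of Th-227 ≈ 85.2 pM, within 1.5% of the printed
86 pM (the unrounded assay IC50 behind the printed 22 is not available).
Daughter ingrowth uses the two-member Bateman form

    A_d(t) = A_p(0) · λ_d/(λ_d − λ_p) · (e^(−λ_p t) − e^(−λ_d t)),

with the limiting form `A_p(0)·λ t·e^(−λt)` when the decay constants are
numerically equal. This is the no-loss upper bound: alpha-recoil
redistribution of the daughter is deliberately not modelled, so measured
tumor Ra-223 is expected to fall below this curve. Useful closed forms:
transient-equilibrium activity ratio λ_d/(λ_d − λ_p) ≈ 2.572; ingrowth
peak at ln(λ_d/λ_p)/(λ_d − λ_p) ≈ 20.9 d; the ratio approaches equilibrium
as 1 − e^(−(λ_d−λ_p)t), i.e. 9.5% short at 100 d and within 1% only from
≈195 d.

## Synthetic data: what it emulates

All generators are pure functions of their spec (seed included); identical
specs give byte-identical tables, and every generated table validates
cleanly against the consuming CSV schema.

**Plates.** Single agents follow programmed 4PLs (defaults: the reported
parental potencies, 22 kBq/mL and 5 µM, unit hill slopes, titrations
0.01–50 kBq/mL and 0.01–25 µM); mixture survival is `(s_A·s_B)^γ` — γ = 1
exactly Bliss-independent, γ > 1 synergistic, γ < 1 antagonistic. This
one-parameter interaction was chosen over mechanistic radiobiology because
its null is exactly known and recoverable. Noise is additive Gaussian on
the viability fraction (default sd 0.05, typical of CellTiter-Glo-class
assays), clipped to [0, 1.2]; signals are emitted on a raw scale with
control and blank wells included. Defaults: 9-point titrations, 3
replicates, 8 controls/blanks. The noisy IC50-recovery experiment uses a
denser 16-point titration with 16 controls/blanks and a steep (hill 2)
curve centred in the range: a design-stage power check showed the absolute
IC50 of a hill-1 curve has ~6–7% relative sd under this noise (the
0.5-of-control crossing flattens as the slope falls), so a curve the
design brackets and resolves is the appropriate calibration target.

**Xenografts.** Volumes solve dV/dt = (g − kill(t))·V in closed form:
exponential growth (default doubling 8.3 d from 90 mm³ at randomization)
minus a radioconjugate kill proportional to dose and decaying with the
Th-227 half-life, and a constant PARP-inhibitor kill during the 28-day
dosing window. Kill coefficients are anchored mid-dose: 300 kBq/kg and
50 mg/kg each halve the tumor burden relative to vehicle by day 21
(`ttc_kill_rate`/`ola_kill_rate` invert the closed form for any other
anchor). Because log-kills add, a ψ = 1 combination arm satisfies Bliss
additivity *exactly* (true combination T/C = product of monotherapy T/Cs),
making ψ = 1 a true null for the call pipeline; ψ > 1 multiplies the
combined kill. The programmed-synergy setting uses ψ ≈ 2.16, making the
300+50 arm's true T/C 0.05 against a Bliss expectation of 0.25 — the same
synergy magnitude as the published knockout calls (0.03 observed vs 0.25
expected). Measurement noise is multiplicative lognormal (sd 0.1 of log
volume); censoring applies at the first measured volume ≥ 1,500 mm³. A
single linear-in-dose kill coefficient cannot reproduce every printed
monotherapy T/C simultaneously (e.g. 600 kBq/kg gives 0.25 here vs printed
0.1–0.3); the generator is a statistical testbed, not a fitted PK/PD model.

**Biodistribution.** Decay-corrected curves in %IA/g: tumor uptake
`plateau·(1 − e^(−0.02 t))` (targeted plateau 50, isotype 5, emulating the
reported 42–59% vs ≤5%), blood clearance bi-exponential (12% at T½ 10 h +
20% at T½ 150 h), giving a tumor/blood ratio ≈ 11.8 at 336 h, in the
reported 12.8–17.3 range. Emitted activities are the curves decayed with
the Th-227 half-life plus lognormal noise (cv 0.1), with harvest times
24/72/168/336 h and n = 3 per point.

**Hematology.** Per-lineage dips are asymmetric Gaussians in time: nadir
day and depth are programmed directly, and the right-hand width is solved
so the curve re-crosses (1 − tolerance)·baseline exactly at the programmed
recovery day. Defaults program the reported high-dose pattern (platelets
0.5× at day 12, recovery day 26; WBC 0.5× at day 11, recovery day 39; RBC
essentially unaffected) plus a milder dip for the low-dose combination.
Sampling every 14 days means detected nadir/recovery days are correct only
to one sampling interval — exactly as in the real design. Noise is
lognormal, cv 0.05.

**What passing these tests does not show.** The generators share the
analysis's structural assumptions (exponential growth, log-additive kills,
4PL viability, independent lognormal noise). Recovery under them
demonstrates correctness of the estimators and calling rules, not
robustness to model misspecification — real tumors regrow, plateau and
drop out non-randomly; plates have edge effects and non-Gaussian outliers.
The published experimental values themselves (IC50s, %IA/g courses, CI
0.6/1) are not re-derivable from raw data since none is deposited; they
enter only as printed inputs to the worked examples.

## Problem sizes

The default test and acceptance runs use 200-replicate Monte-Carlo loops
with 5 animals per arm (7 measurement days, 4 arms) for the Bliss-call
operating characteristics, 200 single-titration refits for IC50 recovery,
and single simulated studies at the design sizes (10/arm, n = 3 per
biodistribution time point) for the worked examples. These sizes give
binomial standard errors ≤ 3.5 percentage points on the reported rates.

## Known limitations

- No response-surface models (ZIP/HSA/BRAID) and no mixed-effects or
  time-to-event analysis of tumor growth; the pipeline mirrors the
  day-wise, ratio-based analysis it re-implements.
- The Tukey step assumes homoscedastic normal volumes at the reference
  day; with strong kill the variance is dose-dependent, which the
  permutation cross-check in the tests only partially probes.
- Bateman ingrowth ignores daughter loss (recoil, redistribution) by
  design — it is the comparison bound, not a prediction.
- `parse_arm_doses` relies on the `ttc-<dose>`/`ola-<dose>` arm-label
  convention; studies with other labels must pass explicit dose maps.
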