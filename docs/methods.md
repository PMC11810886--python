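# Methods

## The inductive targeted-yield model

The package implements the soil-test crop response (STCR) calibration chain
for a single season: a fertility-gradient trial supplies plots spanning a
wide range of soil-test values; from plot-level yield, uptake, soil tests
and applied doses the four basic parameters per nutrient are estimated
(nutrient requirement NR, and the per cent contributions of soil Cs,
fertilizer Cf and farmyard manure Cfym to uptake); the linear prescription
`F = a·T − b·S − c·O` follows algebraically with `a = NR·100/Cf`,
`b = (Cs/Cf)·conv`, `c = (Cfym/Cf)·conv`.

Units and bases are the ones soil-testing practice uses and are applied
exactly once per quantity: fertilizer doses and NR are on the oxide basis
(P2O5, K2O), soil tests, uptakes and manure credits on the element basis;
`conv` = 2.2914 (P→P2O5) and 1.2046 (K→K2O) carries element-basis terms
onto the oxide dose scale. These factors are configurable but their
defaults also back-compute the published soil coefficients (e.g.
`b_P = (11.02/46.62)·2.2914 = 0.54`), which is the internal consistency
check used by the tests.

## Basic-parameter estimators

Estimation is stratified, mirroring the trial structure:

1. **Cs** from control plots (no fertilizer, no manure): `100·U/S` per plot.
2. **Cf** from fertilized, unmanured plots with a positive dose of the
   nutrient: `100·conv·(U − (Cs/100)·S)/F`. Negative plot-level values are
   kept (the mean stays unbiased); a diagnostics counter reports them.
3. **Cfym** from manured plots: the residual uptake after soil and
   fertilizer shares, per kg of manure credit.
4. **NR** from fertilized plots: uptake (oxide basis) per quintal of fresh
   yield.

Plot-level ratios are averaged by default (mean of ratios); a
ratio-of-means variant is available via `method="ratio_of_means"`. Both are
invariant to plot order. Plot-level averaging was chosen as the default
because the small gaps between the reference strip-mean cross-checks
(e.g. NR_N 0.372 from treated means) and the published point values
(0.38) indicate the original calibration averaged per plot.

For NR a second, model-consistent estimator is provided
(`nr_method="closure"`). The generator defines a plot's yield as the
across-nutrient **mean** of the per-nutrient implied yields `U_j·conv_j/NR_j`;
consequently the identity `Σ_j U_j·conv_j/NR_j = 3·Y` holds exactly on
noise-free plots, and solving it for `1/NR_j` by least squares inverts the
generator to machine precision. The classical per-plot ratio `U·conv/Y`
carries a small aggregation bias (1–3% at the reference ground truth)
whenever the three implied yields differ within a plot; it remains the
default because it is the field definition. The zero-noise inversion test
uses the closure estimator and additionally bounds the ratio estimator's
bias.

## The synthetic trial generator

The generator reproduces the experiment's statistical skeleton, not its
agronomy:

- **Strips.** Soil-test values are drawn independently per nutrient and
  plot from per-strip normal distributions truncated at zero. Default means
  (416/435/475 kg/ha N; 184.3/197.4/209.4 P; 515/552/620 K) and CVs
  (≈0.8–2.8%) come from the reference field's strip statistics.
- **Treatments.** The 24-row factorial (4 levels each of N/P2O5/K2O;
  three control replicates) is laid out per strip; treatment order is
  seed-controlled. Each strip splits into three 8-plot manure sub-strips at
  0 / 6.25 / 12.5 t/ha; the three controls always occupy the unmanured
  sub-strip so controls receive neither input.
- **Uptake.** Composed from the contribution fractions:
  `U = (Cs/100)·S + (Cf/100)·F/conv + (Cfym/100)·O`, then multiplied by
  unit-mean log-normal noise (default relative SD 5%; multiplicative
  because uptakes are positive and field CVs are reported relative).
- **Yield.** The across-nutrient mean of implied yields times its own
  log-normal noise. A mean rather than a Liebig minimum keeps every
  nutrient informative about NR and keeps the closure identity linear; the
  choice is deliberate and isolated in one place should a minimum-law
  variant be wanted.
- **Manure credit.** From the manure composition (default: 26% moisture,
  0.56/0.23/0.47% N/P/K on fresh weight; fresh-basis credit, i.e. 70 kg N
  at 12.5 t/ha).

What the generator does **not** emulate: spatial autocorrelation and block
effects, within-plot correlation between the three nutrients' soil tests
(drawn independently; the real field likely correlates them), season and
management covariates, and any nonlinearity or interaction in the response.
Passing recovery tests therefore show that the estimators invert this
generative model at realistic noise, not that they are robust to every
field pathology.

## Prescription, floors, caps, reckoner

Coefficients are stored at full precision; the published form rounds to two
decimals. Dose evaluation clips a negative raw dose at zero, raises
sub-floor doses to the maintenance floor (defaults: 60 kg N, 50 kg K2O, no
P floor) and caps at the highest tested level (180/240/150 kg/ha). Ready
reckoners print whole-kg doses and compute the per cent reduction under
IPNS from those display integers, as published tables do; maintenance and
maximum cells are flagged and rendered with asterisks.

The reference reckoner uses manure credits back-computed from the published
fertilizer savings at 12.5 t/ha (59.68/30.23/53.97 kg N/P/K): those savings
match neither the fresh- nor the dry-basis credit of the stated manure
composition exactly, so the credit triple is an explicit, overridable
configuration value rather than a hidden constant.

## Validation metrics

Per cent achievement is `100·yield/target` with a ±10% acceptance window.
The response ratio divides the yield gain over the **absolute control** by
the summed N+P2O5+K2O doses (manure mass excluded) — the only definition
that reproduces the reference trial's printed ratios. The benefit–cost
ratio needs user-supplied prices; a calibration helper back-solves the
implied produce price and a uniform nutrient cost from two published rows.
For the reference trial this system has no feasible solution (the implied
input cost is negative: the control row's BCR is too low relative to its
yield share), so the helper flags infeasibility and absolute BCRs are not
reproduced — only the formula and the calibration record are provided.

## Numerical and statistical choices

- Sample SD uses the n−1 denominator; a single observation yields an
  undefined (flagged) SD/CV, never zero.
- Gradient verification demands strictly increasing strip means; ties fail.
- The yield regression (OLS on UN, UP, UK, SN, SP, SK, FN, FP2O5, FK2O,
  FYM with intercept) validates its design rank incrementally and names the
  first collinear column; a constant response is reported with R² = 1 and
  zero coefficients.
- All randomness flows through one `numpy` Generator per operation, seeded
  explicitly; equal seeds give byte-identical CSV artifacts.
- Default problem sizes — 72 plots per trial, 100 replicates for recovery
  studies, 10 for Monte-Carlo mean checks — keep any single study well
  under a minute while leaving Monte-Carlo error far below the asserted
  tolerances.

## Known limits

- **Manure-contribution recovery.** At the reference conditions (5% uptake
  noise, 72 plots) Cfym is weakly identified: the manure uptake increment
  (for P, ≈2.5–5 kg/ha at 6.25–12.5 t/ha) is the same order as the noise SD
  on total uptake (≈2.7 kg/ha for P). Measured median relative errors over
  100 replicates are ≈9–17% depending on nutrient and estimator — also for
  a near-efficient joint weighted regression of uptake on soil, fertilizer
  and manure terms — so a ≤10% recovery bound is not attainable from this
  design; the corresponding test
  (`test_parameter_recovery_fym_contribution`) asserts the bound and fails,
  documenting the information limit rather than hiding it. Recovering Cfym
  to that precision would need more manured plots, higher manure rates, or
  lower-noise uptake assays.
- NR's per-plot ratio estimator is mildly biased under the mean-yield
  closure (see above); the closure estimator removes the bias at the cost
  of being tied to the generative yield model.
- The published second-decimal roundings of two target coefficients
  (a_P2O5, a_K2O) are not the roundings of the values their own basic
  parameters imply; the package keeps both forms (derived vs published) and
  the tests compare them within ±0.01.
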