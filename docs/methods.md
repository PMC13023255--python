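# Methods

## Scope and model overview

`fermkin` analyses high-throughput in vitro digestion–fermentation
experiments on swine feeds. A study crosses diets with three
gastric/small-intestinal simulation protocols — shaking flask (S),
dialysis bag (D), and shaking-gastric + dialysis-intestinal (SD) —
then ferments each digestion residue with a fecal inoculum for one or
more durations. Four analysis blocks sit on top of the resulting
tables: stage-wise digestibility accounting, cumulative gas-production
kinetics, in vitro ↔ in vivo agreement, and association statistics
(prediction regressions, starred correlation matrices, factorial
ANOVA with an LSD letter display). A synthetic generator emulates the
whole design so that every block is testable end to end.

## Digestibility accounting

Disappearance mass balances drive everything. For a nutrient with
intake mass `m0·c0` (mass × concentration), GI-phase digestibility is
`100·(m0c0 − m1c1)/(m0c0)` where `(m1, c1)` describe the GI residue.
Fermentative disappearance is reported on two bases: relative to feed
(so GI + fermentative + undigested ≡ 100, an identity the code asserts
to 1e-12) and relative to the GI residue (IVFDMD/IVFCPD, the quantity
used to predict odorants). Both are emitted because both framings are
standard and they answer different questions; neither is privileged.
Dry matter shares the nutrient code path by setting both
concentrations to 100 %.

In vivo apparent total tract digestibility uses acid-insoluble ash as
an internal marker: `ATTD = 100·(1 − (AIA_diet/AIA_feces) ·
(N_feces/N_diet))`. The estimator assumes the marker is completely
indigestible and homogeneously mixed; a unit test verifies it against
an explicit intake/excretion simulation with conserved marker.

Records violating the physical ordering
`ferm residue ≤ GI residue ≤ substrate` (possible under measurement
noise) are flagged and excluded from cell means, never clipped.
Nitrogen-free extract is computed by difference on a dry-matter basis,
`NFE = 100 − (ash + CP + fat + fiber)`; the whole from which the
assayed fractions are subtracted is the dry matter itself (100 %),
which is the only reading consistent with standard proximate
bookkeeping.

## Gas-production kinetics

Cumulative gas follows `G(t) = A/(1 + (C/t)^B)`: `A` (mL) the
asymptotic production (fermentable-substrate pool), `B` (unitless) the
switching sharpness (microbial adaptation), `C` (h) the half-time
(`G(C) = A/2` exactly). Derived quantities:

* `T_max = C·((B−1)/(B+1))^(1/B)`, the time of maximum rate, defined
  only for `B > 1`; for `B ≤ 1` the rate is largest as `t → 0+` and
  `T_max`/`R_max` are reported as undefined (NaN), never forced to 0.
* `R_max`: the form conventionally printed with this model,
  `A·C^B·T^(−B−1)/(1 + C^B·T^(−B))^2`, differs from the analytic
  derivative `dG/dt|T_max` by exactly a factor `B`. Both are emitted
  (`as_printed`, `derivative_consistent`) with explicit labels;
  displays default to the printed form for comparability with the
  literature, and the derivative-consistent form is the one checked
  against a numeric-differentiation oracle. `R_max` is a volume rate
  and is labelled mL/h (reports elsewhere sometimes print h⁻¹).

Fitting is unweighted nonlinear least squares (no weighting scheme is
standard for these records). The RSS surface is multi-modal, so the
fitter multi-starts over a fixed grid — `B ∈ {0.5, 1, 1.5, 2, 3}`,
`C` at the quartiles of the observation times, `A = 1.1·max G` — with
bounds `A ∈ (0, 10·max G]`, `B ∈ (0.05, 10]`, `C ∈ (min t/10,
10·max t]`, keeping the lowest RSS and breaking ties toward smaller
`B`. Observations at `t = 0` are excluded from the residual (the model
is defined there only by its limit). At least 5 positive-time points
are required. Batch fitting never raises on a bad curve; it returns a
`converged=False` record counted in the cell summary. Noiseless curves
are recovered to better than 1e-4 relative from any grid start.

## Agreement statistics

Lin's concordance correlation coefficient is computed with population
(n-denominator) moments, `CCC = 2s_xy/(s_x² + s_y² + (x̄ − ȳ)²)`,
which is bounded by |Pearson r| with equality iff means and variances
match. The 95 % interval applies Fisher's arctanh transform with Lin's
asymptotic variance and back-transforms normal quantiles; the interval
method is an implementation choice (agreement studies rarely state
one), so a percentile bootstrap is available behind
`method="bootstrap"` and the two agree to ~0.02 on well-behaved data.
A Monte-Carlo study in the test suite confirms ~95 % coverage of a
known population CCC. Agreement is graded poor (< 0.90), moderate
(0.90–0.95, boundaries inclusive) or high (> 0.95). Pearson p-values
are two-sided from the t distribution with n − 2 df.

## Association statistics

Prediction equations are simple OLS lines `Y = a + bX` with `X` a
fermentative digestibility and `Y` an odorant concentration or enzyme
activity; inference is the regression F-test. The ANOVA is a balanced
two-way fixed-effects decomposition (method × fermentation time with
interaction); unbalanced designs are rejected explicitly rather than
silently reweighted. `SEM = sqrt(MS_error/n_cell)` is pooled from the
error mean square (a per-cell option exists in
`digestibility_table`'s sd columns). LSD letters: two means differ iff
their difference exceeds `t_{1−α/2,df_e}·sqrt(2·MS_error/n)`; because
this criterion depends only on the absolute difference, letter groups
are the maximal runs of the descending-sorted means within one LSD,
lettered `a`, `b`, … from the largest mean — a deterministic compact
letter display verified against an all-pairs oracle. No multiplicity
adjustment is applied to LSD comparisons or correlation stars
(p < 0.05 `*`, p < 0.01 `**`), matching standard reporting practice
for this design; when every cell is internally constant, `MS_error`
is 0 and letter logic is suppressed with a flag.

## Synthetic study generator

Defaults live in `src/fermkin/data/default_study.yaml` (data, not
code): 6 diets × 3 methods × {12, 48} h × 6 replicates, gas readings
every 0.5 h to 48 h, with per-cell kinetic triples, diet compositions,
in vivo digestibility means, agreement targets and analyte response
lines as shipped study-design values.

* **Gas curves.** Readings are model values plus iid Gaussian error
  passed through a running-maximum register, the natural model of a
  cumulative pressure sensor: the record can never decrease (negative
  increments are truncated to zero), zero noise reproduces the model
  exactly, and — unlike independently clipping noisy increments, which
  inflates a 96-point plateau by tens of mL — the register stays
  mean-consistent with the model, so the asymptote remains
  recoverable (within ~3 % at sd 1 mL). Default reading sd 0.5 mL.
* **Paired digestibility.** Per nutrient, in vivo values are diet
  means plus within-diet noise (default sd 1.5 %, the order of
  replicate dispersion in marker digestibility assays); in vitro
  totals are built from them with configurable population Pearson r
  and a mean shift `δ = sqrt(2r·s_x·s_y/CCC* − s_x² − s_y²)` solved so
  that the population CCC hits its target (`solve_mean_shift_for_ccc`
  inverts exactly the CCC the agreement module computes). The in vitro
  total is split into GI and fermentative stages by a method×nutrient
  GI share expressed as a fraction of the total (so fermentative
  disappearance is never negative); the 12 h time point realises a
  configurable fraction (default 0.65) of the 48 h fermentative
  disappearance. Residue masses/concentrations and in vivo
  marker/nutrient concentrations are then materialised so that the
  downstream mass-balance and marker formulas return the generated
  values exactly.
* **Odorants and enzymes.** `Y = intercept + slope·X + noise` with `X`
  the bottle's fermentative CP digestibility, floored at zero
  (concentrations cannot be negative). Per-analyte noise sds default
  to the replicate-SEM order of magnitude seen in fermentation-fluid
  assays (e.g. 0.7 ppm p-cresol, 25 mM ammonia); these magnitudes are
  assumptions, not measured values.
* **Seeding.** One root seed spawns fixed per-table substreams
  (`default_rng([seed, offset])`), so adding a table never perturbs
  the others; identical config + seed reproduce every CSV byte for
  byte.

With all noise sds at zero and agreement targets r = CCC = 1, the full
pipeline round-trips the generator: fitted kinetic triples,
stage digestibilities, regression coefficients and CCC are recovered
exactly (to float/fit tolerance). This closure is what the test suite
demonstrates; it shows internal consistency of the chain, not that
real digestion data satisfy the generative assumptions (linear
odorant responses, Gaussian noise, a single-pool gas sigmoid,
method-independent in vivo values).

## Numerical choices and degenerate inputs

* Kinetic fits: `scipy.optimize.least_squares` (TRF) with
  `xtol = ftol = 1e-12`; flat-zero curves return a non-converged
  record. Fit results are invariant to observation order.
* CCC at |CCC| = 1 yields a degenerate point interval rather than an
  arctanh overflow; zero-variance series raise informative errors.
* GI residues with zero nutrient make residue-basis fermentative
  digestibility NaN (flagged), feed-basis 0.
* Single-replicate summary cells report sd 0 with a
  `single_replicate` flag.
* Problem sizes in tests and the acceptance script are chosen to keep
  the whole suite in the tens of seconds: 96-point gas grids, ≤ 1000
  Monte-Carlo replicates, and a 2-diet × 2-method × 3-replicate study
  for end-to-end closure.

## Known limitations

* The gas model is single-pool; multi-pool (true multiphasic) sums
  are out of scope.
* The generator ties odorants to fermentative CP digestibility only —
  no mechanistic microbial simulation — and treats in vivo
  digestibility as method-independent truth.
* The ANOVA is fixed-effects on balanced designs; no mixed models or
  repeated-measures covariance structures.
* Printed parameter tables in the literature are rounded to 2
  decimals; derived closed forms (e.g. `T_max`) can only be checked
  against them within input-rounding propagation, and some published
  rows are internally inconsistent under any reading of the formulas.
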