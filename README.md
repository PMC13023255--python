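# fermkin

Analytics for high-throughput **in vitro digestion–fermentation**
evaluation of swine feeds. Animal digestibility trials are slow and
expensive; a common laboratory alternative simulates the stomach and
small intestine enzymatically (by shaking flask **S**, dialysis bag
**D**, or a hybrid **SD**), then ferments the residue with a pig fecal
inoculum while logging cumulative gas. `fermkin` implements the
complete computational chain such an experiment needs:

* **Digestibility accounting** — stage-wise nutrient disappearance
  (GI phase, fermentation phase on feed and residue bases, total
  tract, with the identity `total = GI + fermentative(feed)` enforced),
  nitrogen-free extract by difference
  (`NFE = 100 − (ash + CP + fat + fiber)`, % DM), and marker-based in
  vivo ATTD using acid-insoluble ash:
  `ATTD = 100·(1 − (AIA_diet/AIA_feces)·(N_feces/N_diet))`.
* **Gas kinetics** — least-squares fits of the sigmoid
  `G(t) = A / (1 + (C/t)^B)` with derived
  `T_max = C·((B−1)/(B+1))^(1/B)` and both published variants of the
  maximum rate `R_max` (the conventional closed form and the analytic
  `dG/dt` at `T_max`, which differ by a factor `B`).
* **Agreement** — Pearson r and Lin's concordance correlation
  coefficient `CCC = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²)` with a z-transform
  95 % CI (bootstrap optional) and the poor/moderate/high grading at
  0.90 / 0.95.
* **Association** — OLS prediction equations (odorants and microbial
  enzyme activities vs fermentative CP digestibility), starred Pearson
  correlation matrices, and balanced method × time ANOVA with LSD
  compact-letter displays.
* **Synthetic study generator** — a fully seeded emulation of the
  6-diet × 3-method × 2-time × 6-replicate design with configurable
  noise and agreement targets, so the entire pipeline is testable
  without laboratory data.

Gas-curve fitting and prediction regressions are scikit-learn style
estimators (`GasProductionCurve`, `LinearPredictionEquation`) and
compose with sklearn tooling; everything else is plain functions over
pandas tables.

## Worked example

```python
import numpy as np
from fermkin import GasProductionCurve, agreement_summary, compute_nfe
from fermkin.simulate import simulate_gas_curve

# NFE of a weaning diet from its proximate fractions (% DM)
compute_nfe(ash=4.70, cp=18.17, ee=4.28, cf=2.49)
# 70.36

# fit a noisy synthetic gas curve (true A, B, C = 85.76, 1.27, 3.42)
t = np.arange(0.5, 48.01, 0.5)
g = simulate_gas_curve(85.76, 1.27, 3.42, t, noise_sd=0.5, rng=0)
fit = GasProductionCurve().fit(t, g)
(fit.A_, fit.B_, fit.C_)          # (86.93, 1.235, 3.512)
fit.t_max_                        # 0.566  h
fit.r_max_printed_                # 13.2   mL/h (conventional form)
fit.r_max_derivative_             # 16.3   mL/h (max slope of G)

# agreement between paired in vivo / in vitro digestibility
rng = np.random.default_rng(1)
invivo = rng.normal(82, 2.5, 36)
invitro = invivo - 1.0 + rng.normal(0, 0.8, 36)
agreement_summary(invivo, invitro)
# AgreementResult(r=0.967, p_value=7.0e-22, ccc=0.862,
#                 ci_low=0.777, ci_high=0.916, category='poor', n=36)
```

The asymptote comes back within ~1 % of truth at this noise level; the
agreement example shows how a 1-point systematic bias drags a
precisely correlated method (r ≈ 0.97) down to a "poor" concordance
(CCC ≈ 0.86) — exactly the distinction CCC exists to make.

## Command line

```sh
fermkin simulate --seed 42 --out study/          # five CSV input tables
fermkin run --simulate --seed 42 --out run/      # full pipeline + report
fermkin kinetics --gas study/gas.csv --out fits.csv
fermkin validate --inputs study/
```

`fermkin run` writes per-stage CSVs, a markdown report and a
`manifest.json` (config snapshot, seed, input digests, stage status);
identical seed and config reproduce every output byte for byte. File
schemas are documented in `docs/schemas.md`, the statistical methods
and generator assumptions in `docs/methods.md`.

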