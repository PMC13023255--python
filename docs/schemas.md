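# File schemas

All pipeline inputs and outputs are plain CSV. A study directory holds
the five input tables below; `fermkin run` writes its stage outputs
next to a `manifest.json` that records the config snapshot, seed,
SHA-256 digests of every input, per-stage status and output paths.

## Input tables

### `compositions.csv` — one row per diet

| column | units | meaning |
|---|---|---|
| `diet` | — | diet label (e.g. W1) |
| `dm` | % as-fed | dry matter |
| `ash`, `cp`, `ee`, `cf` | % of DM | ash, crude protein, crude fat, crude fiber |
| `nfe` | % of DM | nitrogen-free extract, `100 − (ash+cp+ee+cf)` |

### `gas.csv` — one row per bottle × reading

| column | units | meaning |
|---|---|---|
| `bottle` | — | unique bottle id |
| `diet`, `method` | — | design keys; method ∈ {S, D, SD} |
| `replicate` | — | replicate index within the cell |
| `time_h` | h | reading time, strictly increasing per bottle |
| `cum_ml` | mL | cumulative gas volume (nondecreasing) |

### `residues.csv` — one row per diet × method × time × replicate

| column | units | meaning |
|---|---|---|
| `diet`, `method`, `time_h`, `replicate` | — | design keys |
| `substrate_dm_g` | g | feed DM charged into digestion |
| `substrate_cp_pct` | % of DM | feed CP concentration |
| `residue_gi_dm_g` | g | residue DM after the gastric+intestinal phase |
| `residue_gi_cp_pct` | % of DM | CP concentration of that residue |
| `residue_ferm_dm_g` | g | residue DM after fermentation |
| `residue_ferm_cp_pct` | % of DM | CP concentration of that residue |

### `fermentation.csv` — long format, one row per sample × analyte

| column | meaning |
|---|---|
| `diet`, `method`, `time_h`, `replicate` | design keys |
| `ivfcpd` | fermentative CP digestibility of the sample (% of GI-residue CP); blank for enzyme rows |
| `analyte` | `p_cresol`, `indole`, `skatole`, `nh3` (odorants; ppm, NH3 mM) or `protease`, `urease` (enzymes) |
| `value` | concentration or activity |
| `kind` | `odorant` or `enzyme` |

### `invivo.csv` — one row per diet × pen

| column | units | meaning |
|---|---|---|
| `diet`, `pen` | — | design keys |
| `aia_diet_pct`, `aia_feces_pct` | % of DM | acid-insoluble ash marker concentrations |
| `cp_diet_pct`, `cp_feces_pct` | % of DM | crude protein concentrations |
| `fecal_<analyte>` | as above | fecal odorants and enzyme activities |

## Stage outputs

* `digestibility.csv` — per record × nutrient: `gi_pct`,
  `ferm_pct_feed`, `ferm_pct_residue`, `total_pct`, `flagged`.
* `digestibility_summary.csv` — per diet × method × time × nutrient
  mean/sd/count of the four quantities, `single_replicate` flag.
* `attd.csv` — marker-based in vivo ATTD per diet × pen × nutrient.
* `kinetic_fits.csv` — per bottle: `A`, `B`, `C`, `t_max`,
  `r_max_printed`, `r_max_derivative`, `rss`, `converged`, `n_points`.
* `kinetics_summary.csv` — per diet × method mean and SEM of the
  parameters plus `n_failed`.
* `agreement.csv` — per nutrient × method × time: `n`, `r`, `p_value`,
  `ccc`, `ci_low`, `ci_high`, `category`.
* `prediction_equations.csv` — per method × response: slope,
  intercept, rendered equation, R², F-test p, n.
* `correlation_r.csv` / `correlation_p.csv` / `correlation_stars.csv`
  — pairwise Pearson matrices over fermentation-fluid analytes.
* `anova_letters.csv` — per diet × analyte × time × method: cell mean,
  LSD letters, pooled SEM and effect p-values.
* `validation.csv`, `report.md`, `manifest.json` — run bookkeeping.
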