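# Default synthetic study: 6 commercial swine diets (weaning W1/W2,
# grower G1/G2, finisher F1/F2) x 3 digestion methods (S shaking,
# D dialysis, SD shaking-gastric + dialysis-intestinal) x 2 fermentation
# times x 6 replicates. Kinetic triples, compositions, in vivo ATTD
# means, agreement targets and prediction lines are study-design data,
# not code constants. Noise magnitudes are modelling assumptions chosen
# to match the dispersion order of magnitude of replicated wet-lab
# digestion assays (see docs/methods.md).
seed: 42
methods: [S, D, SD]
fermentation_times_h: [12, 48]
replicates: 6
gas_sampling_times_h: {start: 0.5, stop: 48.0, step: 0.5}

diets:
  W1: {dm: 87.65, ash: 4.70, cp: 18.17, ee: 4.28, cf: 2.49}
  W2: {dm: 87.92, ash: 5.07, cp: 20.65, ee: 4.46, cf: 2.64}
  G1: {dm: 91.52, ash: 5.79, cp: 18.47, ee: 3.50, cf: 2.76}
  G2: {dm: 90.44, ash: 5.56, cp: 17.67, ee: 3.94, cf: 3.03}
  F1: {dm: 92.96, ash: 4.36, cp: 15.65, ee: 3.32, cf: 3.21}
  F2: {dm: 89.69, ash: 5.36, cp: 17.69, ee: 4.39, cf: 3.16}

# gas model parameters per diet x method: [A (mL), B (-), C (h)]
kinetic_params:
  W1: {S: [85.76, 1.27, 3.42], D: [92.86, 1.32, 8.91], SD: [80.64, 1.01, 5.74]}
  W2: {S: [86.19, 1.43, 6.37], D: [84.96, 2.12, 9.51], SD: [73.24, 1.32, 7.96]}
  G1: {S: [81.29, 1.56, 2.86], D: [70.06, 1.40, 5.18], SD: [64.84, 1.52, 4.73]}
  G2: {S: [95.84, 1.90, 3.88], D: [77.46, 1.06, 7.72], SD: [73.15, 1.26, 3.90]}
  F1: {S: [107.76, 1.25, 4.25], D: [102.50, 0.84, 10.28], SD: [80.05, 1.35, 3.10]}
  F2: {S: [91.52, 2.39, 5.99], D: [89.49, 1.71, 7.12], SD: [75.88, 1.49, 5.42]}

# in vivo apparent total tract digestibility means (% of intake)
invivo_attd:
  W1: {dm: 82.44, cp: 82.32}
  W2: {dm: 84.12, cp: 82.12}
  G1: {dm: 84.17, cp: 74.70}
  G2: {dm: 81.93, cp: 73.28}
  F1: {dm: 83.92, cp: 77.69}
  F2: {dm: 79.02, cp: 74.54}
aia_diet_pct: 1.0

# share of the in vitro total digestibility achieved in the simulated
# gastric + small-intestinal phase; dialysis removes end products so its
# enzymatic phase digests more, shaking leaves more to the fermenters
gi_fraction:
  dm: {S: 0.70, D: 0.85, SD: 0.84}
  cp: {S: 0.70, D: 0.92, SD: 0.90}
# fraction of the 48 h fermentative disappearance realised by each time
ferm_time_fraction: {12: 0.65, 48: 1.0}
# in vivo GI share used to derive the fecal fermentative-CP proxy
vivo_gi_fraction: 0.88

# target population agreement between paired in vivo and in vitro
# total digestibility (per nutrient)
agreement:
  dm: {r: 0.9874, ccc: 0.9760}
  cp: {r: 0.9759, ccc: 0.9524}

# linear response of fermentation-fluid analytes to fermentative CP
# digestibility (X, % of GI-residue CP): Y = slope * X + intercept
odorant_models:
  p_cresol: {slope: 1.4257, intercept: -0.7759}   # ppm
  indole: {slope: 0.1165, intercept: -0.2920}     # ppm
  skatole: {slope: 0.4904, intercept: -1.9544}    # ppm
  nh3: {slope: 1.1159, intercept: 12.7888}        # mM
enzyme_models:
  protease: {slope: 0.1813, intercept: -0.3133}   # ug azocasein/mg protein/min
  urease: {slope: 0.0754, intercept: 0.2124}      # umol NH3/mg protein/min

noise:
  gas_increment_sd_ml: 0.5
  digestibility_sd_pct: 1.5
  odorant_sd:
    p_cresol: 0.7
    indole: 0.3
    skatole: 0.15
    nh3: 25.0
  enzyme_sd:
    protease: 0.2
    urease: 0.1
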