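"""Synthetic study generator.

Emulates the full factorial design of a digestion-method comparison
study — 6 diets x 3 gastric/intestinal protocols (S, D, SD) x 2
fermentation times x replicated bottles — so every downstream stage
(digestibility accounting, gas kinetics, agreement, prediction
regressions) is testable without wet-lab data.

Generative model, per table:

* gas curves follow the sigmoid G = A/(1 + (C/t)^B) per diet x method;
  Gaussian reading noise passes through a running-maximum register
  (negative increments truncated to zero), so observed curves are
  nondecreasing like real pressure-sensor records;
* paired in vivo / in vitro total digestibility is bivariate with a
  configurable population Pearson r and a mean shift solved from the
  target Lin CCC (``solve_mean_shift_for_ccc``); the in vitro total is
  then decomposed into GI and fermentative stages by a method-specific
  GI share and materialised as residue masses, while the in vivo side
  is materialised as marker (AIA) and nutrient concentrations that
  return the exact generated ATTD through the marker formula;
* odorant concentrations and enzyme activities respond linearly to the
  fermentative crude-protein digestibility of the same bottle, plus
  truncated Gaussian noise.

One root seed spawns fixed per-table substreams, so adding a table
never perturbs the others.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import RESIDUE_COLUMNS
from .composition import ProximateComposition
from .kinetics import model_g

__all__ = ["StudyConfig", "StudyTables", "simulate_gas_curve",
           "solve_mean_shift_for_ccc", "simulate_odorants",
           "generate_study", "write_tables", "read_tables"]

_METHODS = ("S", "D", "SD")
# fixed substream offsets per table (root seed spawns these)
_STREAMS = {"gas": 1, "digestibility": 2, "odorant": 3, "enzyme": 4,
            "invivo": 5}

TABLE_FILES = {
    "compositions": "compositions.csv",
    "gas_curves": "gas.csv",
    "residue_records": "residues.csv",
    "fermentation": "fermentation.csv",
    "invivo_records": "invivo.csv",
}


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Complete description of one synthetic study run (see the shipped
    ``data/default_study.yaml`` for field semantics and defaults)."""

    diets: dict
    methods: list
    fermentation_times_h: list
    replicates: int
    gas_sampling_times_h: np.ndarray
    kinetic_params: dict
    invivo_attd: dict
    aia_diet_pct: float
    gi_fraction: dict
    ferm_time_fraction: dict
    vivo_gi_fraction: float
    agreement: dict
    odorant_models: dict
    enzyme_models: dict
    noise: dict
    seed: int = 0

    # -- construction -------------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = copy.deepcopy(raw)
        times = raw["gas_sampling_times_h"]
        if isinstance(times, dict):
            times = np.arange(times["start"],
                              times["stop"] + times["step"] / 2.0,
                              times["step"])
        cfg = cls(
            diets={k: ProximateComposition(**v)
                   for k, v in raw["diets"].items()},
            methods=list(raw["methods"]),
            fermentation_times_h=list(raw["fermentation_times_h"]),
            replicates=int(raw["replicates"]),
            gas_sampling_times_h=np.asarray(times, dtype=float),
            kinetic_params=raw["kinetic_params"],
            invivo_attd=raw["invivo_attd"],
            aia_diet_pct=float(raw.get("aia_diet_pct", 1.0)),
            gi_fraction=raw["gi_fraction"],
            ferm_time_fraction={int(k): float(v) for k, v in
                                raw["ferm_time_fraction"].items()},
            vivo_gi_fraction=float(raw.get("vivo_gi_fraction", 0.88)),
            agreement=raw["agreement"],
            odorant_models=raw["odorant_models"],
            enzyme_models=raw["enzyme_models"],
            noise=raw["noise"],
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls, seed: int | None = None) -> "StudyConfig":
        ref = resources.files("fermkin.data") / "default_study.yaml"
        cfg = cls.from_dict(yaml.safe_load(ref.read_text()))
        if seed is not None:
            cfg.seed = seed
        return cfg

    def validate(self) -> None:
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        bad = [m for m in self.methods if m not in _METHODS]
        if bad:
            raise ConfigError(f"unknown methods {bad}; allowed {_METHODS}")
        t = self.gas_sampling_times_h
        if t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ConfigError("gas sampling times must be strictly "
                              "increasing with first value > 0")
        missing = [(d, m) for d in self.diets for m in self.methods
                   if m not in self.kinetic_params.get(d, {})]
        if missing:
            raise ConfigError(f"kinetic_params missing cells: {missing}")
        for d in self.diets:
            for m in self.methods:
                A, B, C = self.kinetic_params[d][m]
                if min(A, B, C) <= 0:
                    raise ConfigError(f"non-positive kinetic parameter "
                                      f"for {d}/{m}")
        for key in ("gas_increment_sd_ml", "digestibility_sd_pct"):
            if self.noise[key] < 0:
                raise ConfigError(f"noise.{key} must be >= 0")
        for group in ("odorant_sd", "enzyme_sd"):
            if any(v < 0 for v in self.noise[group].values()):
                raise ConfigError(f"noise.{group} values must be >= 0")
        for nutr, tgt in self.agreement.items():
            if not 0 < tgt["r"] <= 1:
                raise ConfigError(f"agreement r for {nutr} outside (0, 1]")

    def noiseless(self) -> "StudyConfig":
        """Copy with every noise sd at zero and exact-agreement targets
        (r = CCC = 1), so the pipeline round-trips the generator."""
        cfg = copy.deepcopy(self)
        cfg.noise["gas_increment_sd_ml"] = 0.0
        cfg.noise["digestibility_sd_pct"] = 0.0
        cfg.noise["odorant_sd"] = {k: 0.0 for k in cfg.noise["odorant_sd"]}
        cfg.noise["enzyme_sd"] = {k: 0.0 for k in cfg.noise["enzyme_sd"]}
        cfg.agreement = {k: {"r": 1.0, "ccc": 1.0} for k in cfg.agreement}
        return cfg

    def rng(self, table: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[table]])


@dataclass
class StudyTables:
    """The linked tables of one study run (all pandas DataFrames)."""

    compositions: pd.DataFrame
    gas_curves: pd.DataFrame
    residue_records: pd.DataFrame
    odorant_records: pd.DataFrame
    enzyme_records: pd.DataFrame
    invivo_records: pd.DataFrame


# -- elementary generators -------------------------------------------

def simulate_gas_curve(A: float, B: float, C: float, times,
                       noise_sd: float = 0.0,
                       rng: np.random.Generator | int | None = None,
                       ) -> np.ndarray:
    """Cumulative gas volumes at ``times`` from the sigmoid model.

    Observation noise emulates a cumulative pressure register: each
    reading is the model value plus iid Gaussian error, and the
    register keeps the running maximum, so per-interval increments are
    truncated at zero and the returned series is nondecreasing, like
    real cumulative sensor records. Unlike independently-clipped
    increment noise, the register accumulates no drift, so the series
    stays mean-consistent with the model and ``noise_sd=0`` reproduces
    it exactly at every time point.
    """
    if min(A, B, C) <= 0:
        raise ValueError("kinetic parameters must be positive")
    times = np.asarray(times, dtype=float)
    if times[0] <= 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and positive")
    clean = model_g(times, A, B, C)
    if noise_sd == 0:
        return clean
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return np.maximum.accumulate(clean
                                 + rng.normal(0.0, noise_sd, clean.size))


def solve_mean_shift_for_ccc(r: float, sd_x: float, sd_y: float,
                             target_ccc: float) -> float:
    """Location shift delta giving population CCC = target at fixed r.

    With population covariance r*sd_x*sd_y and a mean difference delta,
    CCC = 2 r sd_x sd_y / (sd_x^2 + sd_y^2 + delta^2); inverting gives
    delta = sqrt(2 r sd_x sd_y / target - sd_x^2 - sd_y^2). The target
    is feasible only up to 2 r sd_x sd_y / (sd_x^2 + sd_y^2), reached
    at delta = 0.
    """
    if not 0 < r <= 1:
        raise ValueError("r must be in (0, 1]")
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("sds must be positive")
    ccc_max = 2.0 * r * sd_x * sd_y / (sd_x ** 2 + sd_y ** 2)
    if not 0 < target_ccc <= ccc_max + 1e-12:
        raise ValueError(f"target CCC {target_ccc} infeasible; maximum "
                         f"attainable at these r/sds is {ccc_max:.6f}")
    arg = 2.0 * r * sd_x * sd_y / target_ccc - sd_x ** 2 - sd_y ** 2
    return math.sqrt(max(arg, 0.0))


def simulate_odorants(ivfcpd, models: dict, noise_sd,
                      rng: np.random.Generator | int | None = None,
                      ) -> pd.DataFrame:
    """Analyte responses Y = intercept + slope * X + noise, floored at 0.

    ``ivfcpd`` is the fermentative CP digestibility (% of GI-residue CP)
    per observation; ``models`` maps analyte -> {slope, intercept};
    ``noise_sd`` is a scalar or an analyte -> sd mapping.
    """
    x = np.asarray(ivfcpd, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("fermentative digestibility outside [0, 100]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = {}
    for name, m in models.items():
        slope, intercept = float(m["slope"]), float(m["intercept"])
        if not (np.isfinite(slope) and np.isfinite(intercept)):
            raise ValueError(f"non-finite coefficients for {name}")
        sd = noise_sd[name] if isinstance(noise_sd, dict) else noise_sd
        y = intercept + slope * x
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=x.size)
        out[name] = np.maximum(y, 0.0)
    return pd.DataFrame(out)


# -- full study -------------------------------------------------------

def _population_xy(cfg: StudyConfig, nutrient: str):
    """Population moments and shift for one nutrient's paired series."""
    mus = np.array([cfg.invivo_attd[d][nutrient] for d in cfg.diets])
    sd_within = cfg.noise["digestibility_sd_pct"]
    sd = math.sqrt(mus.var() + sd_within ** 2)
    tgt = cfg.agreement[nutrient]
    delta = solve_mean_shift_for_ccc(tgt["r"], sd, sd, tgt["ccc"])
    return mus.mean(), sd, float(tgt["r"]), delta


def generate_study(config: StudyConfig) -> StudyTables:
    """Generate the full linked table set for one study run.

    Identical config + seed give identical tables; sample Pearson r and
    CCC of the paired digestibility converge to the configured targets
    as replicates grow; with all noise at zero the downstream pipeline
    recovers every generating quantity exactly.
    """
    config.validate()
    cfg = config
    diets = list(cfg.diets)
    reps = range(1, cfg.replicates + 1)

    comp_rows = [{"diet": d, "dm": c.dm, "ash": c.ash, "cp": c.cp,
                  "ee": c.ee, "cf": c.cf, "nfe": c.nfe}
                 for d, c in cfg.diets.items()]
    compositions = pd.DataFrame(comp_rows)

    # gas curves (48 h cohort)
    rng_gas = cfg.rng("gas")
    grows = []
    for d in diets:
        for m in cfg.methods:
            A, B, C = cfg.kinetic_params[d][m]
            for rep in reps:
                vols = simulate_gas_curve(
                    A, B, C, cfg.gas_sampling_times_h,
                    cfg.noise["gas_increment_sd_ml"], rng_gas)
                grows.append(pd.DataFrame({
                    "bottle": f"{d}-{m}-{rep}", "diet": d, "method": m,
                    "replicate": rep, "time_h": cfg.gas_sampling_times_h,
                    "cum_ml": vols}))
    gas_curves = pd.concat(grows, ignore_index=True)

    # paired digestibility: in vivo x per diet x rep; in vitro y per
    # diet x method x rep, correlated with x at the configured targets
    rng_dig = cfg.rng("digestibility")
    sd_within = cfg.noise["digestibility_sd_pct"]
    x_vals: dict = {}
    y_vals: dict = {}
    for nutrient in ("dm", "cp"):
        mean_x, sd, r, delta = _population_xy(cfg, nutrient)
        for d in diets:
            mu = cfg.invivo_attd[d][nutrient]
            for rep in reps:
                x = mu + (rng_dig.normal(0.0, sd_within) if sd_within
                          else 0.0)
                x_vals[(nutrient, d, rep)] = x
                for m in cfg.methods:
                    eps = rng_dig.normal() if r < 1 else 0.0
                    y = (mean_x + delta + r * (x - mean_x)
                         + math.sqrt(max(1.0 - r * r, 0.0)) * sd * eps)
                    y_vals[(nutrient, d, m, rep)] = float(np.clip(y, 1.0,
                                                                  99.0))

    # residue records materialising the in vitro digestibilities
    res_rows = []
    for d in diets:
        cp_conc = cfg.diets[d].cp
        for m in cfg.methods:
            for rep in reps:
                y_dm = y_vals[("dm", d, m, rep)]
                y_cp = y_vals[("cp", d, m, rep)]
                gi_dm = cfg.gi_fraction["dm"][m] * y_dm
                gi_cp = cfg.gi_fraction["cp"][m] * y_cp
                for t in cfg.fermentation_times_h:
                    f = cfg.ferm_time_fraction[t]
                    tot_dm = gi_dm + f * (y_dm - gi_dm)
                    tot_cp = gi_cp + f * (y_cp - gi_cp)
                    sub_dm = 4.0
                    cp0 = sub_dm * cp_conc / 100.0
                    r_gi_dm = sub_dm * (1.0 - gi_dm / 100.0)
                    r_gi_cp_mass = cp0 * (1.0 - gi_cp / 100.0)
                    r_f_dm = sub_dm * (1.0 - tot_dm / 100.0)
                    r_f_cp_mass = cp0 * (1.0 - tot_cp / 100.0)
                    res_rows.append({
                        "diet": d, "method": m, "time_h": t,
                        "replicate": rep, "substrate_dm_g": sub_dm,
                        "substrate_cp_pct": cp_conc,
                        "residue_gi_dm_g": r_gi_dm,
                        "residue_gi_cp_pct":
                            100.0 * r_gi_cp_mass / r_gi_dm,
                        "residue_ferm_dm_g": r_f_dm,
                        "residue_ferm_cp_pct":
                            100.0 * r_f_cp_mass / r_f_dm,
                    })
    residue_records = pd.DataFrame(res_rows)[RESIDUE_COLUMNS]

    # fermentation-fluid analytes driven by fermentative CP digestibility
    key = residue_records[["diet", "method", "time_h", "replicate"]]
    gi_cp_mass = (residue_records["residue_gi_dm_g"]
                  * residue_records["residue_gi_cp_pct"])
    f_cp_mass = (residue_records["residue_ferm_dm_g"]
                 * residue_records["residue_ferm_cp_pct"])
    ivfcpd = 100.0 * (gi_cp_mass - f_cp_mass) / gi_cp_mass
    odorant_records = pd.concat(
        [key.reset_index(drop=True),
         simulate_odorants(ivfcpd, cfg.odorant_models,
                           cfg.noise["odorant_sd"], cfg.rng("odorant"))],
        axis=1)
    odorant_records.insert(4, "ivfcpd", ivfcpd.to_numpy())
    enzyme_records = pd.concat(
        [key.reset_index(drop=True),
         simulate_odorants(ivfcpd, cfg.enzyme_models,
                           cfg.noise["enzyme_sd"], cfg.rng("enzyme"))],
        axis=1)

    # in vivo records reproducing x exactly through the marker formula
    rng_vivo = cfg.rng("invivo")
    vivo_rows = []
    for d in diets:
        cp_diet = cfg.diets[d].cp
        for rep in reps:
            x_dm = x_vals[("dm", d, rep)]
            x_cp = x_vals[("cp", d, rep)]
            aia_f = cfg.aia_diet_pct / (1.0 - x_dm / 100.0)
            cp_feces = cp_diet * (1.0 - x_cp / 100.0) / (1.0 - x_dm / 100.0)
            gi_v = cfg.vivo_gi_fraction * x_cp
            x_ferm_vivo = 100.0 * (x_cp - gi_v) / (100.0 - gi_v)
            row = {"diet": d, "pen": rep,
                   "aia_diet_pct": cfg.aia_diet_pct,
                   "aia_feces_pct": aia_f,
                   "cp_diet_pct": cp_diet, "cp_feces_pct": cp_feces}
            fecal = simulate_odorants(
                [x_ferm_vivo],
                cfg.odorant_models | cfg.enzyme_models,
                cfg.noise["odorant_sd"] | cfg.noise["enzyme_sd"],
                rng_vivo)
            row |= {f"fecal_{k}": float(fecal[k].iloc[0])
                    for k in fecal.columns}
            vivo_rows.append(row)
    invivo_records = pd.DataFrame(vivo_rows)

    return StudyTables(compositions=compositions, gas_curves=gas_curves,
                       residue_records=residue_records,
                       odorant_records=odorant_records,
                       enzyme_records=enzyme_records,
                       invivo_records=invivo_records)


# -- I/O --------------------------------------------------------------

def write_tables(tables: StudyTables, out_dir) -> dict:
    """Write the five study CSVs; odorants and enzymes share one long
    ``fermentation.csv`` (columns analyte/kind/value)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    simple = {"compositions": tables.compositions,
              "gas_curves": tables.gas_curves,
              "residue_records": tables.residue_records,
              "invivo_records": tables.invivo_records}
    for name, df in simple.items():
        p = out / TABLE_FILES[name]
        df.to_csv(p, index=False)
        paths[name] = p
    keys = ["diet", "method", "time_h", "replicate"]
    longs = []
    for kind, df in (("odorant", tables.odorant_records),
                     ("enzyme", tables.enzyme_records)):
        value_cols = [c for c in df.columns if c not in keys + ["ivfcpd"]]
        melted = df.melt(id_vars=keys + (["ivfcpd"] if "ivfcpd" in df
                                         else []),
                         value_vars=value_cols, var_name="analyte")
        melted["kind"] = kind
        longs.append(melted)
    ferm = pd.concat(longs, ignore_index=True)
    if "ivfcpd" not in ferm:
        ferm["ivfcpd"] = np.nan
    p = out / TABLE_FILES["fermentation"]
    ferm.to_csv(p, index=False)
    paths["fermentation"] = p
    return paths


def read_tables(in_dir) -> StudyTables:
    """Read a study directory written by :func:`write_tables`."""
    d = Path(in_dir)
    ferm = pd.read_csv(d / TABLE_FILES["fermentation"])
    keys = ["diet", "method", "time_h", "replicate"]

    def pivot(kind):
        sub = ferm[ferm["kind"] == kind]
        wide = sub.pivot_table(index=keys + (["ivfcpd"] if
                                             sub["ivfcpd"].notna().all()
                                             else []),
                               columns="analyte", values="value",
                               sort=False).reset_index()
        wide.columns.name = None
        return wide

    return StudyTables(
        compositions=pd.read_csv(d / TABLE_FILES["compositions"]),
        gas_curves=pd.read_csv(d / TABLE_FILES["gas_curves"]),
        residue_records=pd.read_csv(d / TABLE_FILES["residue_records"]),
        odorant_records=pivot("odorant"),
        enzyme_records=pivot("enzyme"),
        invivo_records=pd.read_csv(d / TABLE_FILES["invivo_records"]),
    )
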