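"""Pipeline orchestration: simulate -> digest -> kinetics -> agree ->
associate, with input validation, a JSON run manifest and a single
human-readable markdown report.

Every stage consumes and produces only documented CSV files (see
docs/schemas.md), so any stage can be re-run in isolation; a fixed seed
and config reproduce the whole run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import agreement_table
from . import association as asmod
from .balance import RESIDUE_COLUMNS, attd_marker, digestibility_table
from .kinetics import kinetics_table
from .simulate import (StudyConfig, TABLE_FILES, generate_study,
                       read_tables, write_tables)

__all__ = ["run_pipeline", "validate_tables", "render_report",
           "RunManifest", "ValidationIssue"]


@dataclass(frozen=True)
class ValidationIssue:
    file: str
    kind: str          # schema | type | integrity
    message: str
    row: int | None = None
    column: str | None = None


@dataclass
class RunManifest:
    seed: int
    config: dict
    software_version: str
    input_digests: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         sort_keys=True, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -- validation -------------------------------------------------------

_SCHEMAS = {
    "compositions.csv": ["diet", "dm", "ash", "cp", "ee", "cf", "nfe"],
    "gas.csv": ["bottle", "diet", "method", "time_h", "cum_ml"],
    "residues.csv": RESIDUE_COLUMNS,
    "fermentation.csv": ["diet", "method", "time_h", "replicate",
                         "ivfcpd", "analyte", "value", "kind"],
    "invivo.csv": ["diet", "pen", "aia_diet_pct", "aia_feces_pct",
                   "cp_diet_pct", "cp_feces_pct"],
}


def validate_tables(input_dir) -> list[ValidationIssue]:
    """Column, type and referential-integrity checks; report only."""
    d = Path(input_dir)
    issues: list[ValidationIssue] = []
    frames: dict[str, pd.DataFrame] = {}
    for fname, cols in _SCHEMAS.items():
        p = d / fname
        if not p.exists():
            issues.append(ValidationIssue(fname, "schema", "file missing"))
            continue
        df = pd.read_csv(p)
        frames[fname] = df
        missing = [c for c in cols if c not in df.columns]
        if missing:
            issues.append(ValidationIssue(
                fname, "schema", f"missing columns {missing}"))

    gas = frames.get("gas.csv")
    if gas is not None and "cum_ml" in gas:
        neg = gas.index[gas["cum_ml"] < 0]
        for i in neg:
            issues.append(ValidationIssue("gas.csv", "type",
                                          "negative cumulative volume",
                                          row=int(i), column="cum_ml"))
        if {"bottle", "time_h"} <= set(gas.columns):
            dup = gas.duplicated(["bottle", "time_h"])
            if dup.any():
                issues.append(ValidationIssue(
                    "gas.csv", "integrity",
                    f"duplicated bottle/time rows: "
                    f"{sorted(gas.loc[dup, 'bottle'].unique())}"))
            nonmono = [b for b, g in gas.groupby("bottle")
                       if np.any(np.diff(g["cum_ml"].to_numpy()) < 0)]
            if nonmono:
                issues.append(ValidationIssue(
                    "gas.csv", "type",
                    f"non-monotone cumulative curves: {nonmono[:5]}"))

    comp = frames.get("compositions.csv")
    if comp is not None and "diet" in comp:
        known = set(comp["diet"])
        for fname in ("gas.csv", "residues.csv", "fermentation.csv",
                      "invivo.csv"):
            df = frames.get(fname)
            if df is not None and "diet" in df:
                orphan = sorted(set(df["diet"]) - known)
                if orphan:
                    issues.append(ValidationIssue(
                        fname, "integrity",
                        f"diets without a composition row: {orphan}"))
    return issues


# -- stages -----------------------------------------------------------

def _stage_digest(tables, out: Path) -> dict:
    long = digestibility_table(tables.residue_records)
    summary = long.attrs["summary"]
    long.to_csv(out / "digestibility.csv", index=False)
    summary.to_csv(out / "digestibility_summary.csv", index=False)

    vivo = tables.invivo_records
    rows = []
    for rec in vivo.itertuples(index=False):
        rows.append({"diet": rec.diet, "pen": rec.pen, "nutrient": "DM",
                     "attd_pct": attd_marker(rec.aia_diet_pct,
                                             rec.aia_feces_pct,
                                             100.0, 100.0)})
        rows.append({"diet": rec.diet, "pen": rec.pen, "nutrient": "CP",
                     "attd_pct": attd_marker(rec.aia_diet_pct,
                                             rec.aia_feces_pct,
                                             rec.cp_diet_pct,
                                             rec.cp_feces_pct)})
    attd = pd.DataFrame(rows)
    attd.to_csv(out / "attd.csv", index=False)
    return {"digestibility": out / "digestibility.csv",
            "digestibility_summary": out / "digestibility_summary.csv",
            "attd": out / "attd.csv"}


def _stage_kinetics(tables, out: Path) -> dict:
    fits = kinetics_table(tables.gas_curves)
    fits.to_csv(out / "kinetic_fits.csv", index=False)
    fits.attrs["summary"].to_csv(out / "kinetics_summary.csv", index=False)
    return {"kinetic_fits": out / "kinetic_fits.csv",
            "kinetics_summary": out / "kinetics_summary.csv"}


def _paired_digestibility(out: Path) -> pd.DataFrame:
    dig = pd.read_csv(out / "digestibility.csv")
    attd = pd.read_csv(out / "attd.csv").rename(
        columns={"pen": "replicate", "attd_pct": "in_vivo"})
    invitro = dig[["diet", "method", "time_h", "replicate", "nutrient",
                   "total_pct"]].rename(columns={"total_pct": "in_vitro"})
    return invitro.merge(attd, on=["diet", "replicate", "nutrient"])


def _stage_agree(out: Path) -> dict:
    pairs = _paired_digestibility(out)
    table = agreement_table(pairs, by=["nutrient", "method",
                                             "time_h"])
    table.to_csv(out / "agreement.csv", index=False)
    return {"agreement": out / "agreement.csv"}


def _stage_associate(tables, out: Path) -> dict:
    keys = ["diet", "method", "time_h", "replicate"]
    odor = tables.odorant_records
    enz = tables.enzyme_records
    analytes = [c for c in odor.columns if c not in keys + ["ivfcpd"]]
    enzymes = [c for c in enz.columns if c not in keys]
    merged = odor.merge(enz, on=keys)

    # prediction equations: analyte ~ fermentative CP digestibility,
    # per method at the terminal fermentation time
    t_end = merged["time_h"].max()
    sub = merged[merged["time_h"] == t_end]
    fits = []
    for m, grp in sub.groupby("method"):
        for a in analytes + enzymes:
            f = asmod.fit_prediction_equation(
                grp["ivfcpd"], grp[a], predictor="IVFCPD", response=a)
            fits.append({"method": m, "response": a, "slope": f.slope,
                         "intercept": f.intercept,
                         "equation": f.equation(),
                         "r_squared": f.r_squared, "p_value": f.p_value,
                         "n": f.n})
    pd.DataFrame(fits).to_csv(out / "prediction_equations.csv",
                              index=False)

    cm = asmod.correlation_matrix(sub[analytes + enzymes])
    cm.r.to_csv(out / "correlation_r.csv")
    cm.p.to_csv(out / "correlation_p.csv")
    cm.stars.to_csv(out / "correlation_stars.csv")

    # method x time ANOVA with LSD letters, per diet x analyte
    arows = []
    for (diet, a), grp in (merged.melt(id_vars=keys,
                                       value_vars=analytes + enzymes,
                                       var_name="analyte")
                           .groupby(["diet", "analyte"])):
        res = asmod.factorial_anova(grp, "value")
        for t_val, letters in res.letters.items():
            for meth, letter in letters.items():
                mean = res.cell_means.loc[
                    (res.cell_means["method"] == meth)
                    & (res.cell_means["time_h"] == t_val), "value"].iloc[0]
                arows.append({"diet": diet, "analyte": a,
                              "time_h": t_val, "method": meth,
                              "mean": mean, "letters": letter,
                              "sem": res.sem,
                              "p_method": res.p["method"],
                              "p_time": res.p["time"],
                              "p_interaction": res.p["interaction"]})
    pd.DataFrame(arows).to_csv(out / "anova_letters.csv", index=False)
    return {"prediction_equations": out / "prediction_equations.csv",
            "correlation_r": out / "correlation_r.csv",
            "correlation_p": out / "correlation_p.csv",
            "correlation_stars": out / "correlation_stars.csv",
            "anova_letters": out / "anova_letters.csv"}


# -- report -----------------------------------------------------------

def render_report(out_dir) -> str:
    """Assemble a markdown report from whatever stage outputs exist.

    Missing sections are noted, never fatal; regeneration from saved
    outputs is idempotent.
    """
    out = Path(out_dir)
    parts = ["# Study report\n"]

    def section(title, fname,
                fmt=lambda df: "```\n" + df.to_string(index=False)
                + "\n```"):
        parts.append(f"\n## {title}\n")
        p = out / fname
        if not p.exists():
            parts.append(f"_section unavailable: {fname} not found_\n")
            return
        df = pd.read_csv(p)
        parts.append(fmt(df.round(4)) + "\n")

    section("Diet composition (% DM)", "inputs/compositions.csv")
    section("Stage digestibility (mean over replicates)",
            "digestibility_summary.csv")
    section("Gas-production kinetics (cell means)", "kinetics_summary.csv")
    section("In vivo vs in vitro agreement", "agreement.csv")
    section("Prediction equations (terminal fermentation time)",
            "prediction_equations.csv")
    text = "".join(parts)
    (out / "report.md").write_text(text)
    return text


# -- orchestration ----------------------------------------------------

def run_pipeline(out_dir, config: StudyConfig | None = None,
                 input_dir=None, simulate: bool = False,
                 seed: int | None = None) -> RunManifest:
    """Run every stage end to end.

    Either ``simulate=True`` (inputs generated from ``config`` into
    ``out_dir/inputs``) or ``input_dir`` pointing at the five study
    CSVs. Raises ``FileNotFoundError``/``ValueError`` on broken inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = StudyConfig.default()
    if seed is not None:
        config.seed = seed

    manifest = RunManifest(seed=config.seed,
                           config=_config_snapshot(config),
                           software_version=_pkg_version("fermkin"))
    if simulate:
        tables = generate_study(config)
        paths = write_tables(tables, out / "inputs")
        input_dir = out / "inputs"
        manifest.stages["simulate"] = "ok"
    elif input_dir is None:
        raise ValueError("either simulate=True or input_dir is required")
    else:
        input_dir = Path(input_dir)
        missing = [f for f in TABLE_FILES.values()
                   if not (input_dir / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"input tables missing from {input_dir}: {missing}")
        manifest.stages["simulate"] = "skipped"

    issues = validate_tables(input_dir)
    manifest.stages["validate"] = ("ok" if not issues else
                                   f"{len(issues)} issue(s)")
    pd.DataFrame([i.__dict__ for i in issues]).to_csv(
        out / "validation.csv", index=False)
    manifest.input_digests = {f: _sha256(input_dir / f)
                              for f in TABLE_FILES.values()}

    tables = read_tables(input_dir)
    for name, stage in (("digest", _stage_digest),
                        ("kinetics", _stage_kinetics)):
        manifest.outputs |= {k: str(v)
                             for k, v in stage(tables, out).items()}
        manifest.stages[name] = "ok"
    manifest.outputs |= {k: str(v) for k, v in _stage_agree(out).items()}
    manifest.stages["agree"] = "ok"
    manifest.outputs |= {k: str(v)
                         for k, v in _stage_associate(tables, out).items()}
    manifest.stages["associate"] = "ok"

    render_report(out)
    manifest.outputs["report"] = str(out / "report.md")
    manifest.stages["report"] = "ok"
    manifest.to_json(out / "manifest.json")
    return manifest


def _config_snapshot(cfg: StudyConfig) -> dict:
    snap = {}
    for k, v in cfg.__dict__.items():
        if isinstance(v, np.ndarray):
            snap[k] = v.tolist()
        elif k == "diets":
            snap[k] = {d: c.__dict__ for d, c in v.items()}
        else:
            snap[k] = v
    return snap
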