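"""Stage-wise digestibility accounting.

The in vitro system digests feed in two blocks — a simulated gastric +
small-intestinal (GI) phase, then a fecal-inoculum fermentation phase —
and each block leaves a residue whose mass and nutrient concentration
are measured. Digestibility of a nutrient in a block is the fraction of
the nutrient entering the block that disappears in it. Two framings are
used for the fermentation phase:

* feed basis — disappearance as % of the nutrient originally ingested,
  so GI + fermentation + undigested = 100 exactly;
* residue basis — disappearance as % of the nutrient entering the
  fermenters (the GI residue), the IVFDMD/IVFCPD quantity used as
  predictor of odorant output.

In vivo, apparent total tract digestibility (ATTD) is estimated with
acid-insoluble ash (AIA) as an indigestible internal marker: the
diet-to-feces ratio of marker concentration indexes how much the
digesta was concentrated, without total collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DigestibilityResult",
    "gi_digestibility",
    "fermentative_digestibility",
    "attd_marker",
    "digestibility_table",
    "stage_digestibilities",
]

#: canonical residues.csv column order
RESIDUE_COLUMNS = [
    "diet", "method", "time_h", "replicate",
    "substrate_dm_g", "substrate_cp_pct",
    "residue_gi_dm_g", "residue_gi_cp_pct",
    "residue_ferm_dm_g", "residue_ferm_cp_pct",
]


@dataclass(frozen=True)
class DigestibilityResult:
    """Stage digestibilities of one nutrient for one digestion run (%)."""

    gi_pct: float
    ferm_pct_feed: float
    ferm_pct_residue: float
    total_pct: float
    flagged: bool = False

    def __post_init__(self) -> None:
        # additive identity holds by construction; assert cheaply
        assert abs(self.total_pct - self.gi_pct - self.ferm_pct_feed) < 1e-9


def gi_digestibility(substrate_dm: float, residue_dm: float,
                     substrate_conc: float = 100.0,
                     residue_conc: float = 100.0) -> float:
    """Disappearance of a nutrient across the GI phase, % of intake.

    ``100 * (m0*c0 - m1*c1) / (m0*c0)`` with masses in g and
    concentrations in % of DM. For dry matter itself pass both
    concentrations as 100 (the default) so the same path serves DM
    and any assayed nutrient.
    """
    if substrate_dm <= 0:
        raise ValueError("substrate mass must be positive")
    intake = substrate_dm * substrate_conc
    if intake == 0:
        raise ZeroDivisionError("substrate nutrient mass is zero; "
                                "digestibility undefined")
    return 100.0 * (intake - residue_dm * residue_conc) / intake


def fermentative_digestibility(substrate_dm: float, substrate_conc: float,
                               gi_dm: float, gi_conc: float,
                               ferm_dm: float, ferm_conc: float,
                               ) -> tuple[float, float]:
    """Fermentation-phase disappearance on feed and residue bases.

    Returns ``(ferm_pct_feed, ferm_pct_residue)``. The residue-basis
    value (IVFDMD/IVFCPD style) is ``nan`` when the GI residue carries
    no nutrient at all — nothing entered the fermenters to disappear.
    """
    feed_mass = substrate_dm * substrate_conc
    gi_mass = gi_dm * gi_conc
    ferm_mass = ferm_dm * ferm_conc
    if feed_mass == 0:
        raise ZeroDivisionError("substrate nutrient mass is zero")
    removed = gi_mass - ferm_mass
    feed_basis = 100.0 * removed / feed_mass
    residue_basis = 100.0 * removed / gi_mass if gi_mass > 0 else float("nan")
    return feed_basis, residue_basis


def attd_marker(aia_diet: float, aia_feces: float,
                nutrient_diet: float, nutrient_feces: float) -> float:
    """Marker-based apparent total tract digestibility, %.

    ``100 * (1 - (aia_diet/aia_feces) * (nutrient_feces/nutrient_diet))``;
    all four are concentrations (% of DM). The AIA ratio converts fecal
    nutrient concentration back to an amount per unit of feed eaten,
    assuming the marker is completely indigestible.
    """
    if min(aia_diet, aia_feces, nutrient_diet) <= 0:
        raise ZeroDivisionError("marker math needs positive diet/feces AIA "
                                "and positive diet nutrient concentration")
    if nutrient_feces < 0:
        raise ValueError("negative fecal nutrient concentration")
    return 100.0 * (1.0 - (aia_diet / aia_feces)
                    * (nutrient_feces / nutrient_diet))


def stage_digestibilities(substrate_dm: float, substrate_conc: float,
                          gi_dm: float, gi_conc: float,
                          ferm_dm: float, ferm_conc: float,
                          ) -> DigestibilityResult:
    """All four stage quantities for one record; flags impossible mass
    ordering (residue growing across a stage) instead of failing."""
    flagged = not (0.0 <= ferm_dm * ferm_conc <= gi_dm * gi_conc + 1e-9
                   <= substrate_dm * substrate_conc + 2e-9)
    gi = gi_digestibility(substrate_dm, gi_dm, substrate_conc, gi_conc)
    feed_b, res_b = fermentative_digestibility(
        substrate_dm, substrate_conc, gi_dm, gi_conc, ferm_dm, ferm_conc)
    return DigestibilityResult(gi_pct=gi, ferm_pct_feed=feed_b,
                               ferm_pct_residue=res_b,
                               total_pct=gi + feed_b, flagged=flagged)


def digestibility_table(residues: pd.DataFrame,
                        drop_flagged: bool = True) -> pd.DataFrame:
    """Per-record stage digestibilities plus per-cell summaries.

    ``residues`` follows the ``residues.csv`` schema (RESIDUE_COLUMNS).
    Returns a long frame with one row per record x nutrient (DM, CP)
    carrying gi_pct / ferm_pct_feed / ferm_pct_residue / total_pct and a
    ``flagged`` column; attach ``.attrs['summary']`` with the
    diet x method x time x nutrient mean and sd, and
    ``.attrs['missing_cells']`` listing empty design cells.
    Physically inconsistent records are excluded from the summary means
    (never silently clipped) when ``drop_flagged``.
    """
    missing = [c for c in RESIDUE_COLUMNS if c not in residues.columns]
    if missing:
        raise ValueError(f"residue table missing columns: {missing}")
    rows = []
    for rec in residues.itertuples(index=False):
        for nutrient, s_c, g_c, f_c in (
                ("DM", 100.0, 100.0, 100.0),
                ("CP", rec.substrate_cp_pct, rec.residue_gi_cp_pct,
                 rec.residue_ferm_cp_pct)):
            r = stage_digestibilities(
                rec.substrate_dm_g, s_c,
                rec.residue_gi_dm_g, g_c,
                rec.residue_ferm_dm_g, f_c)
            rows.append({
                "diet": rec.diet, "method": rec.method,
                "time_h": rec.time_h, "replicate": rec.replicate,
                "nutrient": nutrient, "gi_pct": r.gi_pct,
                "ferm_pct_feed": r.ferm_pct_feed,
                "ferm_pct_residue": r.ferm_pct_residue,
                "total_pct": r.total_pct, "flagged": r.flagged,
            })
    long = pd.DataFrame(rows)
    use = long[~long["flagged"]] if drop_flagged else long
    value_cols = ["gi_pct", "ferm_pct_feed", "ferm_pct_residue", "total_pct"]
    summary = (use.groupby(["diet", "method", "time_h", "nutrient"])
               [value_cols].agg(["mean", "std", "count"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    # single-replicate cells: sd is undefined; report 0 with a flag
    n_col = "total_pct_count"
    single = summary[n_col] == 1
    for c in value_cols:
        summary.loc[single, f"{c}_std"] = 0.0
    summary["single_replicate"] = single
    summary = summary.reset_index()

    expected = residues[["diet", "method", "time_h"]].drop_duplicates()
    got = summary[["diet", "method", "time_h"]].drop_duplicates()
    merged = expected.merge(got, how="left", indicator=True)
    long.attrs["summary"] = summary
    long.attrs["missing_cells"] = merged[merged["_merge"] == "left_only"] \
        .drop(columns="_merge")
    return long
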