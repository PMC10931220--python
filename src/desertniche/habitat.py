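"""Habitat productivity/concealment indices and the plot x factor table.

Five shrub-layer indicators per plot:

    AH   = (LH + MH + SH) / 3          average height (cm)
    Den  = IN / 100 m^2                density per 100 m^2 quadrat
    C    = (3.14 * SR^2 * Den) / 100   coverage (%), SR in metres
    TC.S = sum_i C_i                   total shrub coverage (%)
    TB   = (P * DW * Den) / 100        biomass (g/m^2)

SR (canopy radius) is recorded in cm and converted to metres before the
coverage formula, the only unit reading under which C is a sane ground
fraction; the constant 3.14 is used verbatim rather than pi.  Community
diversity uses the standard Shannon (natural log), Gini–Simpson (1 - sum
p^2), and Pielou (H / ln S) forms.

The assembled factor table has one row per (plot, season, year) and 31
columns: 7 biotic (rodent diversity D.R/E.R/H.R and the four species'
populations ZW/SZ/MZ/WZ) and 24 abiotic (vegetation structure, soil
moisture/hardness by depth layer, monthly meteorology).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cmr import SEASON_MONTH

logger = logging.getLogger(__name__)

#: rodent species codes: M. meridianus, D. sagitta, P. roborovskii, O. sibirica
SPECIES_CODES = ("ZW", "SZ", "MZ", "WZ")

BIOTIC_FACTORS = ["D.R", "E.R", "H.R", "ZW", "SZ", "MZ", "WZ"]
ABIOTIC_FACTORS = [
    "AH.G", "AH.S", "D.G", "D.S", "Den.G", "Den.S", "E.G", "E.S",
    "H.G", "H.S", "HSL1", "HSL2", "HSL3", "HSL4", "YD1", "YD2", "YD3", "YD4",
    "TB.G", "TB.S", "TC.S", "SD", "WD", "RZ",
]
FACTOR_COLUMNS = BIOTIC_FACTORS + ABIOTIC_FACTORS  # 31 columns


def average_height(lh: float, mh: float, sh: float) -> float:
    """Mean of the large/medium/small shrub class heights (cm).

    A missing (NaN) class is excluded from the mean; negative heights are
    rejected.
    """
    vals = np.array([lh, mh, sh], dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("heights must be non-negative")
    if np.isnan(vals).all():
        return float("nan")
    return float(np.nanmean(vals))


def shrub_density(count: int, area_m2: float = 100.0) -> float:
    """Individuals per 100 m^2 of quadrat area."""
    if area_m2 <= 0:
        raise ValueError("quadrat area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / area_m2 * 100.0


def species_coverage(sr_cm: float, den: float) -> float:
    """Per-species shrub coverage in percent of ground area.

    sr_cm: canopy radius in cm (converted to m); den: density per 100 m^2.
    """
    if sr_cm < 0 or den < 0:
        raise ValueError("radius and density must be non-negative")
    sr_m = sr_cm / 100.0
    fraction = 3.14 * sr_m ** 2 * den / 100.0
    return fraction * 100.0


def total_coverage(per_species_c) -> float:
    """Total shrub coverage: the sum of per-species coverages (%)."""
    c = np.asarray(list(per_species_c), dtype=float)
    if c.size and (c < 0).any():
        raise ValueError("coverages must be non-negative")
    tot = float(c.sum()) if c.size else 0.0
    if tot > 100.0:
        logger.warning("total coverage %.1f%% exceeds 100%% "
                       "(overlapping canopies)", tot)
    return tot


def shrub_biomass(p: float, dw: float, den: float) -> float:
    """Shrub biomass (g/m^2) from branch fraction P, dry weight and density."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("branch fraction P must be within [0, 1]")
    if dw < 0 or den < 0:
        raise ValueError("dry weight and density must be non-negative")
    return p * dw * den / 100.0


def diversity_indices(abundances) -> tuple[float, float, float]:
    """(Shannon H, Gini–Simpson D, Pielou E) of an abundance vector.

    H = -sum p ln p; D = 1 - sum p^2; E = H / ln S with S the number of
    species present (E is NaN when S = 1).
    """
    n = np.asarray(abundances, dtype=float)
    if (n < 0).any():
        raise ValueError("abundances must be non-negative")
    total = n.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = n[n > 0] / total
    h = float(-(p * np.log(p)).sum())
    d = float(1.0 - (p ** 2).sum())
    s = p.size
    e = float("nan") if s == 1 else h / np.log(s)
    return h, d, float(e)


KEY = ["plot_id", "season", "year"]


def _shrub_block(shrub: pd.DataFrame) -> pd.DataFrame:
    """Per-plot shrub factors from quadrat records (3 quadrats averaged)."""
    rows = []
    for keys, grp in shrub.groupby(KEY, sort=True):
        per_sp = grp.groupby("species").agg(
            count=("count", "mean"),
            area=("quadrat_area", "mean"),
            lh=("height_large", "mean"), mh=("height_medium", "mean"),
            sh=("height_small", "mean"), sr=("canopy_radius", "mean"),
            p=("branch_fraction", "mean"), dw=("dry_weight", "mean"),
        )
        den = np.array([shrub_density(c, a)
                        for c, a in zip(per_sp["count"], per_sp["area"])])
        ah = np.array([average_height(l, m, s) for l, m, s
                       in zip(per_sp["lh"], per_sp["mh"], per_sp["sh"])])
        cov = np.array([species_coverage(sr, d)
                        for sr, d in zip(per_sp["sr"], den)])
        tb = np.array([shrub_biomass(p, dw, d) for p, dw, d
                       in zip(per_sp["p"], per_sp["dw"], den)])
        h, d, e = diversity_indices(per_sp["count"].to_numpy())
        rows.append({**dict(zip(KEY, keys)),
                     "AH.S": float(np.nanmean(ah)), "Den.S": float(den.sum()),
                     "TC.S": total_coverage(cov), "TB.S": float(tb.sum()),
                     "H.S": h, "D.S": d, "E.S": e})
    return pd.DataFrame(rows)


def _herb_block(herb: pd.DataFrame) -> pd.DataFrame:
    """Per-plot grass factors from 1 m^2 quadrat records."""
    rows = []
    for keys, grp in herb.groupby(KEY, sort=True):
        per_sp = grp.groupby("species").agg(
            count=("count", "mean"), height=("height", "mean"),
            dw=("dry_weight", "mean"), area=("quadrat_area", "mean"),
        )
        h, d, e = diversity_indices(per_sp["count"].to_numpy())
        rows.append({**dict(zip(KEY, keys)),
                     "AH.G": float(per_sp["height"].mean()),
                     "Den.G": float((per_sp["count"] / per_sp["area"]).sum()),
                     "TB.G": float((per_sp["dw"] / per_sp["area"]).sum()),
                     "H.G": h, "D.G": d, "E.G": e})
    return pd.DataFrame(rows)


def _soil_block(soil: pd.DataFrame) -> pd.DataFrame:
    """Soil moisture/hardness columns, one per 5 cm depth layer (1-4)."""
    agg = soil.groupby(KEY + ["layer"], sort=True).agg(
        moisture=("moisture_pct", "mean"), hardness=("hardness", "mean"),
    ).reset_index()
    wide_m = agg.pivot_table(index=KEY, columns="layer", values="moisture")
    wide_h = agg.pivot_table(index=KEY, columns="layer", values="hardness")
    out = pd.DataFrame(index=wide_m.index)
    for layer in (1, 2, 3, 4):
        out[f"HSL{layer}"] = wide_m[layer] if layer in wide_m else np.nan
        out[f"YD{layer}"] = wide_h[layer] if layer in wide_h else np.nan
        if layer not in wide_m.columns or layer not in wide_h.columns:
            logger.warning("soil layer %d missing; column left as NaN", layer)
    return out.reset_index()


def _rodent_block(mnka_df: pd.DataFrame) -> pd.DataFrame:
    """Rodent populations and community diversity per plot."""
    wide = mnka_df.pivot_table(index=KEY, columns="species", values="mnka",
                               aggfunc="sum", fill_value=0)
    out = pd.DataFrame(index=wide.index)
    for code in SPECIES_CODES:
        out[code] = wide[code] if code in wide.columns else 0
    div = []
    for _, row in wide.iterrows():
        if row.sum() == 0:
            div.append((np.nan, np.nan, np.nan))
        else:
            div.append(diversity_indices(row.to_numpy()))
    out[["H.R", "D.R", "E.R"]] = pd.DataFrame(
        div, index=wide.index, columns=["H.R", "D.R", "E.R"])
    return out.reset_index()


def assemble_factor_table(shrub: pd.DataFrame, herb: pd.DataFrame,
                          soil: pd.DataFrame, meteo: pd.DataFrame,
                          rodent_mnka: pd.DataFrame) -> pd.DataFrame:
    """Join all measurement sources into the (plot, season, year) x 31 table.

    Quadrat replicates are averaged per plot; soil depth layers stay as
    separate columns; missing cells are left NaN (never imputed) with a
    warning.  Meteorology is keyed by (year, month) and joined through the
    season's trapping month (spring/summer/autumn -> April/July/October).
    """
    blocks = [_rodent_block(rodent_mnka), _shrub_block(shrub),
              _herb_block(herb), _soil_block(soil)]
    table = blocks[0]
    for blk in blocks[1:]:
        table = table.merge(blk, on=KEY, how="outer")
    table["season"] = table["season"].astype(str).str.lower()
    table["month"] = table["season"].map(SEASON_MONTH)

    met = meteo.copy()
    for col in ("year", "month"):
        met[col] = met[col].astype(int)
    need = set(zip(table["year"].astype(int), table["month"]))
    have = set(zip(met["year"], met["month"]))
    unmapped = sorted(need - have)
    if unmapped:
        raise ValueError(f"meteorology missing for (year, month): {unmapped}")
    table = table.merge(met[["year", "month", "WD", "SD", "RZ"]],
                        on=["year", "month"], how="left")
    table = table.drop(columns="month")

    missing_cols = [c for c in FACTOR_COLUMNS if c not in table.columns]
    for c in missing_cols:
        table[c] = np.nan
    if missing_cols:
        logger.warning("factor columns with no source data: %s", missing_cols)
    n_missing = int(table[FACTOR_COLUMNS].isna().sum().sum())
    if n_missing:
        logger.warning("factor table has %d missing cell(s); not imputed",
                       n_missing)
    return table[KEY + FACTOR_COLUMNS].sort_values(KEY).reset_index(drop=True)
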