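"""Spatial niche breadth and niche overlap indices.

Niche breadth of species *i* over r resource levels (the trapping plots) is
the Shannon–Wiener index normalised to [0, 1]:

    B_i = [lg(Σ_j N_ij) − (1/Σ_j N_ij) Σ_j N_ij·lg(N_ij)] / lg(r)

with lg the base-10 logarithm and N_ij the use of plot j by species i
(per-plot MNKA here).  Algebraically B_i = H/ln(r) for Shannon entropy H of
the use proportions, so it is 1 for uniform use, 0 when a single plot is
used, and invariant to the log base.

Niche overlap between species i and k (Colwell–Futuyma/Schoener form):

    O_ik = 1 − ½ Σ_j |N_ij/N_i − N_kj/N_k|

i.e. one minus half the L1 distance between the two plot-use proportion
vectors: 1 for proportionally identical use, 0 for disjoint plots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ResourceUseMatrix:
    """Species x plots matrix of non-negative use values N_ij."""

    species: list[str]
    plots: list[str]
    values: np.ndarray  # species x plots, >= 0
    season: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), len(self.plots)):
            raise ValueError("values shape must be (n_species, n_plots)")
        if (self.values < 0).any():
            raise ValueError("use values must be non-negative")

    @property
    def r(self) -> int:
        """Number of resource levels (plots)."""
        return len(self.plots)


@dataclass
class NicheSummary:
    """Mean +/- standard error of an index across years for one season."""

    species: str
    season: str
    mean: float
    se: float
    n_years: int


def breadth(use_row, log_base: float = 10.0) -> float:
    """Normalised Shannon–Wiener spatial niche breadth, in [0, 1].

    Zero-use plots contribute nothing; an all-zero row is undefined and
    returns NaN with a warning.  The log base cancels in the normalisation.
    """
    n = np.asarray(use_row, dtype=float)
    if n.ndim != 1:
        raise ValueError("use_row must be 1-D")
    if (n < 0).any():
        raise ValueError("use values must be non-negative")
    r = n.size
    if r < 2:
        raise ValueError("breadth needs at least 2 resource levels (log r = 0)")
    total = n.sum()
    if total == 0:
        logger.warning("all-zero use vector: niche breadth undefined")
        return float("nan")
    log = lambda x: np.log(x) / math.log(log_base)  # noqa: E731
    pos = n[n > 0]
    return float((log(total) - (pos * log(pos)).sum() / total) / log(r))


def overlap(use_i, use_k) -> float:
    """Niche overlap O_ik in [0, 1]; NaN with a warning for a zero-sum input."""
    a = np.asarray(use_i, dtype=float)
    b = np.asarray(use_k, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("use vectors must be 1-D and of equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("use values must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        logger.warning("zero-sum use vector: niche overlap undefined")
        return float("nan")
    return float(1.0 - 0.5 * np.abs(a / a.sum() - b / b.sum()).sum())


def overlap_matrix(use: ResourceUseMatrix) -> pd.DataFrame:
    """Symmetric species x species overlap matrix (diagonal 1 where defined)."""
    if len(use.species) < 2:
        raise ValueError("overlap matrix needs at least 2 species")
    k = len(use.species)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            out[i, j] = out[j, i] = overlap(use.values[i], use.values[j])
    return pd.DataFrame(out, index=use.species, columns=use.species)


def summarize_by_season(per_year_values: dict[int, float], season: str,
                        species: str = "") -> NicheSummary:
    """Mean and standard error (sd/sqrt(n)) of per-year index values.

    NaN years (species absent) are excluded with a logged count; a single
    year gives se = 0.
    """
    if not per_year_values:
        raise ValueError("no per-year values to summarize")
    vals = np.array(list(per_year_values.values()), dtype=float)
    ok = vals[~np.isnan(vals)]
    n_dropped = vals.size - ok.size
    if n_dropped:
        logger.info("dropping %d undefined year value(s) for %s/%s",
                    n_dropped, species, season)
    if ok.size == 0:
        raise ValueError("all per-year values are undefined")
    se = 0.0 if ok.size == 1 else float(np.std(ok, ddof=1) / np.sqrt(ok.size))
    return NicheSummary(species=species, season=season,
                        mean=float(ok.mean()), se=se, n_years=int(ok.size))


def use_matrix_from_mnka(mnka_df: pd.DataFrame, season: str, year: int,
                         species: list[str] | None = None,
                         plots: list[str] | None = None) -> ResourceUseMatrix:
    """Build the N_ij matrix for one (season, year) from the MNKA table."""
    sub = mnka_df[(mnka_df["season"] == season) & (mnka_df["year"] == year)]
    wide = sub.pivot_table(index="species", columns="plot_id", values="mnka",
                           aggfunc="sum", fill_value=0)
    if species is None:
        species = sorted(wide.index)
    if plots is None:
        plots = sorted(wide.columns)
    wide = wide.reindex(index=species, columns=plots, fill_value=0)
    return ResourceUseMatrix(species=list(species), plots=list(plots),
                             values=wide.to_numpy(dtype=float),
                             season=season, year=int(year))


def breadth_table(mnka_df: pd.DataFrame) -> pd.DataFrame:
    """Per-(species, season, year) niche breadth from the MNKA table."""
    rows = []
    species = sorted(mnka_df["species"].unique())
    plots = sorted(mnka_df["plot_id"].unique())
    for (year, season), _ in mnka_df.groupby(["year", "season"], sort=True):
        use = use_matrix_from_mnka(mnka_df, season, int(year), species, plots)
        for i, sp in enumerate(use.species):
            rows.append({"species": sp, "season": season, "year": int(year),
                         "breadth": breadth(use.values[i])})
    return pd.DataFrame(rows, columns=["species", "season", "year", "breadth"])


def overlap_table(mnka_df: pd.DataFrame) -> pd.DataFrame:
    """Per-(pair, season, year) niche overlap from the MNKA table."""
    rows = []
    species = sorted(mnka_df["species"].unique())
    plots = sorted(mnka_df["plot_id"].unique())
    for (year, season), _ in mnka_df.groupby(["year", "season"], sort=True):
        use = use_matrix_from_mnka(mnka_df, season, int(year), species, plots)
        mat = overlap_matrix(use) if len(species) >= 2 else None
        if mat is None:
            continue
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                rows.append({"species_a": a, "species_b": b, "season": season,
                             "year": int(year), "overlap": mat.loc[a, b]})
    return pd.DataFrame(rows, columns=["species_a", "species_b", "season",
                                       "year", "overlap"])


def summarize_index_table(df: pd.DataFrame, value_col: str,
                          group_cols: list[str]) -> pd.DataFrame:
    """Collapse per-year values to mean ± se rows (the published table shape)."""
    rows = []
    for keys, grp in df.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        per_year = dict(zip(grp["year"], grp[value_col]))
        try:
            s = summarize_by_season(per_year, season=dict(zip(group_cols, keys)).get("season", ""))
        except ValueError:
            continue
        rows.append({**dict(zip(group_cols, keys)), "mean": s.mean,
                     "se": s.se, "n_years": s.n_years})
    return pd.DataFrame(rows)
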