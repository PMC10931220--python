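"""Synthetic trapping-study generator with known latent truth.

Emulates a desert small-mammal capture-mark-recapture design: 24 one-hectare
plots, each with a 7 x 8 live-trap grid checked twice daily for 4 consecutive
days, in spring/summer/autumn of five consecutive years.

Per species and year, plot occupancy is a symmetric Dirichlet draw whose
concentration alpha acts as an evenness dial — high alpha gives near-uniform
use (spatial niche breadth near 1), low alpha concentrates the population on
few plots.  Individuals carry persistent PIT-style IDs, survive between
sessions with a configurable probability (so the bracketing "b" term of MNKA
is exercised), and are detected per trap check as independent Bernoulli
trials.  Environment tables (shrub and herb quadrats, soil layers, monthly
meteorology) are generated with a configurable linear linkage between chosen
habitat factors and species densities, plus Gaussian noise, so that
downstream factor screening and constrained ordination have a known answer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cmr import CHECKS, SEASON_MONTH, SEASONS
from .niche import breadth

logger = logging.getLogger(__name__)

SHRUB_SPECIES = ("caragana", "nitraria", "reaumuria")
HERB_SPECIES = ("stipa", "allium", "peganum")

#: (baseline, natural scale) of each habitat knob the generator controls;
#: linked factors add scale * (sum of coefficient x standardized density).
FACTOR_KNOBS: dict[str, tuple[float, float]] = {
    "AH.S": (40.0, 8.0),   # shrub height, cm
    "AH.G": (12.0, 3.0),   # grass height, cm
    "Den.G": (80.0, 15.0),  # grass density, plants/m^2
    "TB.G": (30.0, 6.0),   # grass biomass, g/m^2
    "HSL1": (8.0, 1.5), "HSL2": (10.0, 1.5),
    "HSL3": (12.0, 1.5), "HSL4": (14.0, 1.5),   # soil moisture, %
    "YD1": (12.0, 2.0), "YD2": (16.0, 2.0),
    "YD3": (20.0, 2.0), "YD4": (24.0, 2.0),     # soil hardness
}


@dataclass
class SimulationConfig:
    """Study design and latent parameters of a virtual trapping study."""

    n_plots: int = 24
    grid_rows: int = 7
    grid_cols: int = 8
    n_days: int = 4
    years: tuple[int, ...] = (2017, 2018, 2019, 2020, 2021)
    seasons: tuple[str, ...] = SEASONS
    species: tuple[str, ...] = ("SZ", "WZ", "MZ", "ZW")
    #: expected total individuals per species per season (all plots pooled)
    abundance: dict[str, int] = field(default_factory=lambda: {
        "SZ": 90, "WZ": 40, "MZ": 60, "ZW": 140})
    #: Dirichlet concentration of plot occupancy (evenness dial); ordered so
    #: that MZ (P. roborovskii) has the narrowest spatial niche
    alpha: dict[str, float] = field(default_factory=lambda: {
        "SZ": 4.0, "WZ": 4.0, "MZ": 0.8, "ZW": 10.0})
    p_capture: float = 0.25          # per trap check, per individual
    survival: float = 0.7            # between consecutive sessions in a year
    survival_winter: float = 0.7     # across the winter gap (0 = hibernators)
    trailing_buffer_session: bool = False
    effective_area_ha: float = 1.0
    n_quadrats: int = 3
    #: factor -> {species code: coefficient} linear environment linkage
    linked_factors: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"AH.S": {"WZ": 1.0}, "HSL2": {"SZ": 0.8}})
    noise_sd: float = 1.0            # environment noise, standardized units
    seed: int = 0

    def __post_init__(self) -> None:
        for sp, a in self.alpha.items():
            if a <= 0:
                raise ValueError(f"alpha must be positive (species {sp})")
        if not 0.0 <= self.p_capture <= 1.0:
            raise ValueError("p_capture must be in [0, 1]")
        for s in (self.survival, self.survival_winter):
            if not 0.0 <= s <= 1.0:
                raise ValueError("survival must be in [0, 1]")
        for sp, n in self.abundance.items():
            if n < 0:
                raise ValueError(f"abundance must be >= 0 (species {sp})")

    @property
    def n_traps(self) -> int:
        return self.grid_rows * self.grid_cols

    def trap_days(self) -> int:
        """Total cage-days of the design: traps x plots x days x sessions."""
        return (self.n_traps * self.n_plots * self.n_days
                * len(self.seasons) * len(self.years))

    def sessions(self) -> list[tuple[int, str]]:
        out = [(y, s) for y in self.years for s in self.seasons]
        if self.trailing_buffer_session:
            out.append((max(self.years) + 1, self.seasons[0]))
        return out


@dataclass
class SimulationTruth:
    """Latent state of a simulated study, for estimator-recovery tests."""

    abundance: pd.DataFrame          # species, plot_id, year, season, n_true
    occupancy: dict[tuple[str, int], np.ndarray]  # (species, year) -> probs
    true_breadth: pd.DataFrame       # species, year, breadth of occupancy
    linked_factors: dict[str, dict[str, float]]

    def to_json(self, path) -> None:
        payload = {
            "abundance": self.abundance.to_dict(orient="records"),
            "occupancy": {f"{sp}|{yr}": w.tolist()
                          for (sp, yr), w in self.occupancy.items()},
            "true_breadth": self.true_breadth.to_dict(orient="records"),
            "linked_factors": self.linked_factors,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _plot_ids(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def simulate_study(config: SimulationConfig, seed: int | None = None,
                   ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate the capture-record table and its latent truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    plots = _plot_ids(config.n_plots)
    sessions = config.sessions()

    occupancy: dict[tuple[str, int], np.ndarray] = {}
    breadth_rows = []
    target: dict[tuple[str, int, str], np.ndarray] = {}
    for sp in config.species:
        for year in sorted({y for y, _ in sessions}):
            w = rng.dirichlet(np.full(config.n_plots, config.alpha[sp]))
            occupancy[(sp, year)] = w
            breadth_rows.append({
                "species": sp, "year": year,
                "breadth": breadth(w) if config.n_plots >= 2
                else float("nan")})
            for season in config.seasons:
                if (year, season) in sessions:
                    target[(sp, year, season)] = rng.multinomial(
                        config.abundance[sp], w)

    records = []
    truth_rows = []
    counter = 0
    n_checks = config.n_days * len(CHECKS)
    for sp in config.species:
        alive: dict[str, list[str]] = {p: [] for p in plots}
        prev_year: int | None = None
        for year, season in sessions:
            surv = (config.survival if year == prev_year
                    else config.survival_winter)
            for pi, plot in enumerate(plots):
                pool = alive[plot]
                if prev_year is not None:
                    keep = rng.random(len(pool)) < surv
                    pool = [i for i, k in zip(pool, keep) if k]
                n_target = int(target[(sp, year, season)][pi])
                if len(pool) > n_target:
                    idx = rng.choice(len(pool), size=n_target, replace=False)
                    pool = [pool[i] for i in sorted(idx)]
                while len(pool) < n_target:
                    counter += 1
                    pool.append(f"{sp}-{counter:06d}")
                alive[plot] = pool
                truth_rows.append({"species": sp, "plot_id": plot,
                                   "year": year, "season": season,
                                   "n_true": n_target})
                for ind in pool:
                    hits = np.flatnonzero(rng.random(n_checks)
                                          < config.p_capture)
                    for h in hits:
                        records.append({
                            "year": year, "season": season, "plot_id": plot,
                            "day": int(h // 2) + 1, "check": CHECKS[h % 2],
                            "station_row": int(rng.integers(config.grid_rows)),
                            "station_col": int(rng.integers(config.grid_cols)),
                            "species": sp, "individual_id": ind,
                        })
            prev_year = year

    captures = pd.DataFrame(records, columns=[
        "year", "season", "plot_id", "day", "check", "station_row",
        "station_col", "species", "individual_id"])
    truth = SimulationTruth(
        abundance=pd.DataFrame(truth_rows),
        occupancy=occupancy,
        true_breadth=pd.DataFrame(breadth_rows),
        linked_factors={k: dict(v) for k, v in config.linked_factors.items()},
    )
    logger.info("simulated %d capture records over %d cage-days",
                len(captures), config.trap_days())
    return captures, truth


def _knob_values(config: SimulationConfig, truth: SimulationTruth,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Latent per-(plot, season, year) value of every habitat knob.

    Linked knobs are baseline + scale * (sum coef * z-scored density +
    Gaussian noise); unlinked knobs are baseline + scale * noise.
    """
    dens = truth.abundance.pivot_table(
        index=["plot_id", "season", "year"], columns="species",
        values="n_true", aggfunc="sum", fill_value=0)
    z = (dens - dens.mean()) / dens.std(ddof=0).replace(0, 1.0)
    out = pd.DataFrame(index=dens.index)
    for factor, (base, scale) in FACTOR_KNOBS.items():
        signal = np.zeros(len(dens))
        for sp, coef in config.linked_factors.get(factor, {}).items():
            if sp not in z.columns:
                raise ValueError(f"linked species {sp} not simulated")
            signal = signal + coef * z[sp].to_numpy()
        noise = rng.normal(0.0, config.noise_sd, size=len(dens))
        out[factor] = base + scale * (signal + noise)
    unknown = set(config.linked_factors) - set(FACTOR_KNOBS)
    if unknown:
        raise ValueError(f"no generator knob for linked factor(s): "
                         f"{sorted(unknown)}")
    return out


def simulate_environment(config: SimulationConfig, truth: SimulationTruth,
                         seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Generate shrub, herb, soil and meteorology tables for the study."""
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1)
    knobs = _knob_values(config, truth, rng)
    q_noise = 0.1 * config.noise_sd  # replicate-level jitter, relative
    shrub_rows, herb_rows, soil_rows = [], [], []
    # height multipliers of the large/medium/small classes average to 1,
    # so plot-mean shrub height reproduces the AH.S knob exactly
    class_mult = (1.5, 1.0, 0.5)
    sr_base = {s: v for s, v in zip(SHRUB_SPECIES, (45.0, 30.0, 20.0))}
    p_frac = {s: v for s, v in zip(SHRUB_SPECIES, (0.15, 0.20, 0.10))}
    dw_base = {s: v for s, v in zip(SHRUB_SPECIES, (400.0, 250.0, 150.0))}

    for (plot, season, year), row in knobs.iterrows():
        for q in range(1, config.n_quadrats + 1):
            for s_sp in SHRUB_SPECIES:
                jit = 1.0 + q_noise * rng.normal()
                ah = max(row["AH.S"] * jit, 1.0)
                shrub_rows.append({
                    "plot_id": plot, "season": season, "year": year,
                    "quadrat_id": q, "quadrat_area": 100.0, "species": s_sp,
                    "count": int(rng.poisson(2.0)) + 1,
                    "height_large": ah * class_mult[0],
                    "height_medium": ah * class_mult[1],
                    "height_small": ah * class_mult[2],
                    "canopy_radius": sr_base[s_sp] * (1 + q_noise
                                                      * rng.normal()),
                    "branch_fraction": p_frac[s_sp],
                    "dry_weight": dw_base[s_sp] * (1 + q_noise
                                                   * rng.normal()),
                })
            for h_sp in HERB_SPECIES:
                herb_rows.append({
                    "plot_id": plot, "season": season, "year": year,
                    "quadrat_id": q, "quadrat_area": 1.0, "species": h_sp,
                    "height": max(row["AH.G"]
                                  * (1 + q_noise * rng.normal()), 0.5),
                    "count": int(rng.poisson(
                        max(row["Den.G"], 1.0) / len(HERB_SPECIES))),
                    "dry_weight": max(row["TB.G"] / len(HERB_SPECIES)
                                      * (1 + q_noise * rng.normal()), 0.0),
                })
        for layer in (1, 2, 3, 4):
            soil_rows.append({
                "plot_id": plot, "season": season, "year": year,
                "layer": layer,
                "moisture_pct": max(row[f"HSL{layer}"], 0.1),
                "hardness": max(row[f"YD{layer}"], 0.1),
            })

    wd_base, sd_base, rz_base = ({4: 12.0, 7: 25.0, 10: 8.0},
                                 {4: 30.0, 7: 45.0, 10: 40.0},
                                 {4: 280.0, 7: 300.0, 10: 260.0})
    meteo_rows = []
    for year in sorted({y for y, _ in config.sessions()}):
        for month in sorted(set(SEASON_MONTH.values())):
            meteo_rows.append({
                "year": year, "month": month,
                "WD": wd_base[month] + rng.normal(0, 1.0),
                "SD": sd_base[month] + rng.normal(0, 3.0),
                "RZ": rz_base[month] + rng.normal(0, 15.0),
            })

    return {"shrub": pd.DataFrame(shrub_rows),
            "herb": pd.DataFrame(herb_rows),
            "soil": pd.DataFrame(soil_rows),
            "meteo": pd.DataFrame(meteo_rows)}


def write_bundle(outdir, captures: pd.DataFrame,
                 env: dict[str, pd.DataFrame],
                 truth: SimulationTruth) -> dict[str, Path]:
    """Write the full CSV bundle plus truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"captures": outdir / "captures.csv",
             "shrub": outdir / "shrub_quadrats.csv",
             "herb": outdir / "herb_quadrats.csv",
             "soil": outdir / "soil.csv",
             "meteo": outdir / "meteo.csv",
             "truth": outdir / "truth.json"}
    captures.to_csv(paths["captures"], index=False)
    env["shrub"].to_csv(paths["shrub"], index=False)
    env["herb"].to_csv(paths["herb"], index=False)
    env["soil"].to_csv(paths["soil"], index=False)
    env["meteo"].to_csv(paths["meteo"], index=False)
    truth.to_json(paths["truth"])
    return paths
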