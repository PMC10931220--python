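"""End-to-end pipeline: captures -> MNKA -> niche metrics -> screening -> RDA.

Stages and their written artifacts (all CSV/JSON, 6 significant digits):

1. capture records -> per-(species, plot) histories -> ``mnka.csv``
2. per-(season, year) resource-use matrices -> ``niche_breadth.csv``,
   ``niche_overlap.csv`` and their mean ± se summaries
3. quadrat/soil/meteorology tables -> ``factor_table.csv`` (31 factors)
4. per-species random-forest screening with shadow thresholds ->
   ``screening_report.json``; pooled selection -> VIF filter ->
   ``vif_report.json``
5. Hellinger-transformed species block vs standardized retained factors:
   RDA, global permutation test, per-factor fit and forward selection ->
   ``rda_result.json`` + ``table4.csv``

A manifest (seed, config, package version, output hashes) makes reruns
verifiable: the same config and seed reproduce byte-identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cmr import build_histories, log_transform, mnka_table, read_captures
from .habitat import FACTOR_COLUMNS, SPECIES_CODES, assemble_factor_table
from .niche import breadth_table, overlap_table, summarize_index_table
from .ordination import (factor_fit, forward_select, hellinger,
                         permutation_test, rda_fit, standardize)
from .screening import importance_screen, vif_filter
from .simulate import SimulationConfig, simulate_environment, simulate_study

logger = logging.getLogger(__name__)

KEY = ["plot_id", "season", "year"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; seed is mandatory."""

    seed: int
    outdir: str = "desertniche_out"
    captures: str | None = None
    shrub: str | None = None
    herb: str | None = None
    soil: str | None = None
    meteo: str | None = None
    simulation: SimulationConfig | None = None
    effective_area_ha: float = 1.0
    log_base: float = 10.0
    vif_threshold: float = 10.0
    alpha: float = 0.05
    n_permutations: int = 999
    n_trees: int = 300
    grid_rows: int = 7
    grid_cols: int = 8
    one_based_stations: bool = False

    def __post_init__(self) -> None:
        if self.vif_threshold <= 0 or self.n_permutations <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every available stage; returns the in-memory artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    truth = None

    if config.simulation is not None:
        captures, truth = simulate_study(config.simulation, seed=config.seed)
        env = simulate_environment(config.simulation, truth, seed=config.seed)
        shrub, herb, soil, meteo = (env["shrub"], env["herb"], env["soil"],
                                    env["meteo"])
        logger.info("simulated study: %d cage-days, %d capture records",
                    config.simulation.trap_days(), len(captures))
    else:
        if config.captures is None:
            raise ValueError("either a captures path or a simulation config "
                             "is required")
        captures = read_captures(config.captures, config.grid_rows,
                                 config.grid_cols, config.one_based_stations)
        shrub = pd.read_csv(config.shrub) if config.shrub else None
        herb = pd.read_csv(config.herb) if config.herb else None
        soil = pd.read_csv(config.soil) if config.soil else None
        meteo = pd.read_csv(config.meteo) if config.meteo else None

    # stage 1: capture histories and MNKA
    histories = build_histories(captures, config.grid_rows, config.grid_cols,
                                validate=config.simulation is None)
    mnka_df = mnka_table(histories, config.effective_area_ha)
    artifacts["mnka"] = mnka_df
    _write_csv(mnka_df, outdir / "mnka.csv")

    # stage 2: niche breadth and overlap, per year then mean ± se per season
    breadth_df = breadth_table(mnka_df)
    overlap_df = overlap_table(mnka_df)
    artifacts["breadth"] = breadth_df
    artifacts["overlap"] = overlap_df
    _write_csv(breadth_df, outdir / "niche_breadth.csv")
    _write_csv(overlap_df, outdir / "niche_overlap.csv")
    _write_csv(summarize_index_table(breadth_df, "breadth",
                                     ["species", "season"]),
               outdir / "niche_breadth_summary.csv")
    _write_csv(summarize_index_table(overlap_df, "overlap",
                                     ["species_a", "species_b", "season"]),
               outdir / "niche_overlap_summary.csv")

    env_available = all(t is not None for t in (shrub, herb, soil, meteo))
    if not env_available:
        logger.warning("environment tables absent: screening and ordination "
                       "stages skipped")
    else:
        factors = assemble_factor_table(shrub, herb, soil, meteo, mnka_df)
        artifacts["factor_table"] = factors
        _write_csv(factors, outdir / "factor_table.csv")

        # rows with undefined factors (e.g. single-species communities have
        # no evenness) are excluded from screening/ordination, not imputed
        rows_ok = factors[FACTOR_COLUMNS].notna().all(axis=1)
        if (~rows_ok).any():
            logger.warning("excluding %d row(s) with undefined factor "
                           "values from screening/ordination",
                           int((~rows_ok).sum()))
        factors = factors[rows_ok].reset_index(drop=True)
        usable = [c for c in FACTOR_COLUMNS if factors[c].nunique() > 1]
        dropped = sorted(set(FACTOR_COLUMNS) - set(usable))
        if dropped:
            logger.warning("constant factors unusable for screening: %s",
                           dropped)

        # stage 4: per-species screening, pooled selection, VIF filter
        species = [s for s in SPECIES_CODES if s in set(mnka_df["species"])]
        reports = {}
        pooled: list[str] = []
        for i, sp in enumerate(species):
            y = log_transform(factors[sp].to_numpy())
            X = factors[[c for c in usable if c != sp]]
            rep = importance_screen(X, y, n_trees=config.n_trees,
                                    seed=config.seed + i, response=sp)
            reports[sp] = rep.to_dict()
            chosen = rep.very_high_set or rep.high_set
            pooled.extend(c for c in chosen if c not in pooled)
        (outdir / "screening_report.json").write_text(
            json.dumps(reports, indent=1))
        artifacts["screening"] = reports

        vif_rep = vif_filter(factors[pooled], config.vif_threshold) \
            if len(pooled) >= 2 else None
        retained = vif_rep.retained if vif_rep else pooled
        (outdir / "vif_report.json").write_text(json.dumps(
            vif_rep.to_dict() if vif_rep else {"retained": retained},
            indent=1))
        artifacts["vif"] = vif_rep

        # stage 5: Hellinger RDA + permutation inference + forward selection
        use = factors.set_index(KEY)[list(species)]
        nonzero = use.sum(axis=1) > 0
        n_dropped = int((~nonzero).sum())
        if n_dropped:
            logger.info("dropping %d all-zero community row(s) before the "
                        "Hellinger transform", n_dropped)
        use = use[nonzero]
        Xf = factors.set_index(KEY).loc[use.index, retained]
        Y = hellinger(use.to_numpy())
        Xs = pd.DataFrame(standardize(Xf.to_numpy()), columns=retained,
                          index=Xf.index)

        result = rda_fit(Y, Xs.to_numpy(), factor_names=retained)
        perm = permutation_test(Y, Xs.to_numpy(),
                                n_permutations=config.n_permutations,
                                seed=config.seed)
        steps, _sel = forward_select(Y, Xs, alpha=config.alpha,
                                     n_permutations=config.n_permutations,
                                     seed=config.seed)
        fit_tab = factor_fit(result, Xs,
                             n_permutations=config.n_permutations,
                             seed=config.seed)
        step_map = {s.factor: s for s in steps}
        fit_tab["fs_r2"] = [getattr(step_map.get(f), "r2_contribution",
                                    np.nan) for f in fit_tab["factor"]]
        fit_tab["fs_F"] = [getattr(step_map.get(f), "pseudo_F", np.nan)
                           for f in fit_tab["factor"]]
        fit_tab["fs_p"] = [getattr(step_map.get(f), "p_value", np.nan)
                           for f in fit_tab["factor"]]
        _write_csv(fit_tab, outdir / "table4.csv")
        rda_payload = {
            "canonical_eigenvalues": result.canonical_eigenvalues.tolist(),
            "residual_eigenvalues": result.residual_eigenvalues.tolist(),
            "proportion_explained_per_axis":
                result.proportion_explained_per_axis.tolist(),
            "cumulative_first_two": result.cumulative_first_two,
            "r2": result.r2, "adjusted_r2": result.adjusted_r2,
            "n_samples": result.n_samples, "n_factors": result.n_factors,
            "permutation": {"pseudo_F": perm.pseudo_F,
                            "p_value": perm.p_value,
                            "n_permutations": perm.n_permutations,
                            "seed": perm.seed},
            "forward_selection": [dataclasses.asdict(s) for s in steps],
            "retained_factors": retained,
        }
        (outdir / "rda_result.json").write_text(
            json.dumps(rda_payload, indent=1))
        artifacts["rda"] = rda_payload
        artifacts["table4"] = fit_tab

    if truth is not None:
        truth.to_json(outdir / "truth.json")
        artifacts["truth"] = truth
    manifest = {
        "package": "desertniche", "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "outputs": {p.name: _hash_file(p) for p in sorted(outdir.iterdir())
                    if p.suffix in {".csv", ".json"}
                    and p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = manifest
    return artifacts
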