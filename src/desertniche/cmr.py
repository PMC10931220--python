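"""Capture-mark-recapture core: capture records, per-session histories, MNKA.

A trapping *session* is one (year, season, plot) block of four consecutive
trapping days with two trap checks per day.  Abundance per session is
estimated by the minimum number known alive (MNKA):

    MNKA(t) = a + b

where ``a`` is the number of distinct individuals actually caught during
session *t* and ``b`` is the number of previously marked individuals caught
both before and after session *t* but not during it.  MNKA is a lower bound
on true abundance; its negative bias is largest at the first and last
sessions of a study (no bracketing information exists there, so b = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS: tuple[str, ...] = ("spring", "summer", "autumn")
SEASON_ORDER: dict[str, int] = {s: i for i, s in enumerate(SEASONS)}
#: trapping month of each season, used to join monthly meteorology
SEASON_MONTH: dict[str, int] = {"spring": 4, "summer": 7, "autumn": 10}
CHECKS: tuple[str, ...] = ("morning", "afternoon")

CAPTURE_COLUMNS = [
    "year", "season", "plot_id", "day", "check",
    "station_row", "station_col", "species", "individual_id",
]


@dataclass(frozen=True, order=True)
class SessionKey:
    """Chronological key of one trapping session.

    Ordering is (year, season) with spring < summer < autumn; ``plot_id``
    does not participate in the chronological order.
    """

    year: int
    season_index: int = field(compare=True)
    plot_id: str = field(compare=False, default="")

    @classmethod
    def of(cls, year: int, season: str, plot_id: str = "") -> "SessionKey":
        return cls(int(year), SEASON_ORDER[season], plot_id)

    @property
    def season(self) -> str:
        return SEASONS[self.season_index]


@dataclass
class CaptureHistory:
    """Boolean individuals x sessions matrix for one species on one plot.

    ``matrix[i, t]`` is True when individual i was caught at least once
    during session t (within-session recaptures collapse to one presence).
    Columns are chronologically ordered and cover the full study span,
    including sessions with zero captures for this species.
    """

    species: str
    plot_id: str
    matrix: np.ndarray  # bool, individuals x sessions
    individual_ids: list[str]
    sessions: list[tuple[int, str]]  # (year, season), chronological

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ValueError("capture history matrix must be 2-D")
        if self.matrix.shape[0] != len(self.individual_ids):
            raise ValueError("row count must match individual_ids")

    @property
    def n_sessions(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]


def _validate_captures(df: pd.DataFrame, grid_rows: int, grid_cols: int,
                       one_based_stations: bool) -> pd.DataFrame:
    missing = [c for c in CAPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"capture table is missing columns: {missing}")
    df = df.copy()
    df["season"] = df["season"].astype(str).str.lower()
    bad_season = sorted(set(df["season"]) - set(SEASONS))
    if bad_season:
        raise ValueError(f"unknown season tokens: {bad_season}")
    df["check"] = df["check"].astype(str).str.lower()
    bad_check = sorted(set(df["check"]) - set(CHECKS))
    if bad_check:
        raise ValueError(f"unknown check tokens: {bad_check}")
    for col in ("year", "day", "station_row", "station_col"):
        df[col] = df[col].astype(int)
    if one_based_stations:
        df["station_row"] -= 1
        df["station_col"] -= 1
    if ((df["day"] < 1) | (df["day"] > 4)).any():
        bad = df.loc[(df["day"] < 1) | (df["day"] > 4), "day"].unique()
        raise ValueError(f"trap day out of range 1-4: {sorted(bad)}")
    row_bad = (df["station_row"] < 0) | (df["station_row"] >= grid_rows)
    col_bad = (df["station_col"] < 0) | (df["station_col"] >= grid_cols)
    if (row_bad | col_bad).any():
        raise ValueError(
            f"station index outside the {grid_rows}x{grid_cols} grid in "
            f"{int((row_bad | col_bad).sum())} record(s)"
        )
    # one PIT tag = one animal = one species, always
    sp_per_id = df.groupby("individual_id")["species"].nunique()
    conflicted = sp_per_id[sp_per_id > 1]
    if len(conflicted):
        raise ValueError(
            "conflicting species for individual_id(s): "
            + ", ".join(conflicted.index.astype(str))
        )
    return df


def read_captures(path, grid_rows: int = 7, grid_cols: int = 8,
                  one_based_stations: bool = False) -> pd.DataFrame:
    """Read and validate a captures.csv table (UTF-8, header required)."""
    df = pd.read_csv(path)
    return _validate_captures(df, grid_rows, grid_cols, one_based_stations)


def study_sessions(records: pd.DataFrame) -> list[tuple[int, str]]:
    """Chronological (year, season) session axis spanning the records.

    Every season of every year between the first and last observed year is
    included, so species absent in a session still get an all-false column.
    """
    if len(records) == 0:
        return []
    years = range(int(records["year"].min()), int(records["year"].max()) + 1)
    return [(y, s) for y in years for s in SEASONS]


def build_histories(records: pd.DataFrame, grid_rows: int = 7,
                    grid_cols: int = 8, one_based_stations: bool = False,
                    validate: bool = True,
                    ) -> dict[tuple[str, str], CaptureHistory]:
    """Group capture records into per-(species, plot) capture histories."""
    if validate:
        records = _validate_captures(records, grid_rows, grid_cols,
                                     one_based_stations)
    sessions = study_sessions(records)
    if not sessions:
        return {}
    sess_idx = {ys: t for t, ys in enumerate(sessions)}
    out: dict[tuple[str, str], CaptureHistory] = {}
    for (species, plot), grp in records.groupby(["species", "plot_id"],
                                                sort=True):
        ids = sorted(grp["individual_id"].unique())
        id_idx = {i: k for k, i in enumerate(ids)}
        mat = np.zeros((len(ids), len(sessions)), dtype=bool)
        rows = grp["individual_id"].map(id_idx).to_numpy()
        cols = [sess_idx[(y, s)] for y, s in zip(grp["year"], grp["season"])]
        mat[rows, cols] = True
        out[(str(species), str(plot))] = CaptureHistory(
            species=str(species), plot_id=str(plot), matrix=mat,
            individual_ids=list(ids), sessions=list(sessions),
        )
    return out


def mnka(history: CaptureHistory, session_index: int) -> int:
    """Minimum number known alive at one session: a + b.

    a = individuals caught during the session; b = marked individuals caught
    at some earlier AND some later session but not at this one.
    """
    n_sess = history.n_sessions
    if not 0 <= session_index < n_sess:
        raise IndexError(
            f"session_index {session_index} out of range 0..{n_sess - 1}"
        )
    m = history.matrix
    at = m[:, session_index]
    before = m[:, :session_index].any(axis=1)
    after = m[:, session_index + 1:].any(axis=1)
    a = int(at.sum())
    b = int((before & after & ~at).sum())
    return a + b


def mnka_series(history: CaptureHistory) -> np.ndarray:
    """MNKA for every session of the history (first/last have b = 0)."""
    if history.n_sessions == 0:
        raise ValueError("history has no sessions")
    return np.array([mnka(history, t) for t in range(history.n_sessions)],
                    dtype=int)


def density(count: int, effective_area_ha: float = 1.0) -> float:
    """Individuals per hectare from a session count."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if effective_area_ha <= 0:
        raise ValueError("effective area must be positive")
    return count / effective_area_ha


def log_transform(n) -> np.ndarray | float:
    """The log10(n + 1) preprocessing transform; applied only on request."""
    n = np.asarray(n, dtype=float)
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.log10(n + 1.0)
    return float(out) if out.ndim == 0 else out


def mnka_table(histories: dict[tuple[str, str], CaptureHistory],
               effective_area_ha: float = 1.0) -> pd.DataFrame:
    """Long table of MNKA and density per (year, season, plot, species)."""
    rows = []
    for (species, plot), hist in sorted(histories.items()):
        series = mnka_series(hist)
        for (year, season), count in zip(hist.sessions, series):
            rows.append({
                "year": year, "season": season, "plot_id": plot,
                "species": species, "mnka": int(count),
                "density_per_ha": density(int(count), effective_area_ha),
            })
    return pd.DataFrame(
        rows, columns=["year", "season", "plot_id", "species", "mnka",
                       "density_per_ha"])
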