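import numpy as np
import pandas as pd
import pytest

from desertniche import SimulationConfig, simulate_environment, simulate_study


def make_record(year=2017, season="spring", plot="P01", day=1,
                check="morning", row=0, col=0, species="SZ", ind="SZ-1"):
    return {"year": year, "season": season, "plot_id": plot, "day": day,
            "check": check, "station_row": row, "station_col": col,
            "species": species, "individual_id": ind}


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_captures(rng):
    """~200 random but valid capture records across 2 years x 3 seasons."""
    seasons = ("spring", "summer", "autumn")
    rows = []
    for _ in range(200):
        sp = rng.choice(["SZ", "MZ"])
        rows.append(make_record(
            year=int(rng.choice([2017, 2018])),
            season=str(rng.choice(seasons)),
            plot=f"P{int(rng.integers(1, 4)):02d}",
            day=int(rng.integers(1, 5)),
            check=str(rng.choice(["morning", "afternoon"])),
            row=int(rng.integers(0, 7)), col=int(rng.integers(0, 8)),
            species=sp, ind=f"{sp}-{int(rng.integers(1, 30)):03d}"))
    return pd.DataFrame(rows)


SMALL_SIM = dict(
    n_plots=8, years=(2017, 2018),
    abundance={"SZ": 40, "WZ": 20, "MZ": 25, "ZW": 60},
    alpha={"SZ": 4.0, "WZ": 4.0, "MZ": 0.8, "ZW": 10.0},
)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    cfg = SimulationConfig(**SMALL_SIM)
    captures, truth = simulate_study(cfg, seed=11)
    env = simulate_environment(cfg, truth, seed=11)
    return cfg, captures, truth, env
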