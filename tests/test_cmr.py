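"""Capture-history construction and MNKA estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desertniche import (CaptureHistory, build_histories, density,
                         log_transform, mnka, mnka_series, mnka_table)
from conftest import make_record


def mnka_oracle(matrix: np.ndarray, t: int) -> int:
    """Exhaustive per-individual enumeration of the a + b definition."""
    count = 0
    for row in matrix:
        caps = np.flatnonzero(row)
        if t in caps:
            count += 1
        elif caps.size and caps.min() < t < caps.max():
            count += 1
    return count


def history_of(matrix) -> CaptureHistory:
    matrix = np.asarray(matrix, dtype=bool)
    seasons = ("spring", "summer", "autumn")
    sessions = [(2017 + t // 3, seasons[t % 3])
                for t in range(matrix.shape[1])]
    return CaptureHistory(species="SZ", plot_id="P01", matrix=matrix,
                          individual_ids=[f"SZ-{i}" for i in
                                          range(matrix.shape[0])],
                          sessions=sessions)


class TestBuildHistories:
    def test_empty_input_gives_empty_map(self):
        empty = pd.DataFrame(columns=["year", "season", "plot_id", "day",
                                      "check", "station_row", "station_col",
                                      "species", "individual_id"])
        assert build_histories(empty) == {}

    def test_within_session_recaptures_collapse(self):
        records = pd.DataFrame([
            make_record(day=1, check="morning"),
            make_record(day=3, check="afternoon"),
        ])
        hist = build_histories(records)[("SZ", "P01")]
        assert hist.matrix.sum() == 1
        assert hist.n_individuals == 1

    def test_matches_brute_force_grouping_oracle(self, random_captures):
        histories = build_histories(random_captures)
        sessions = sorted(
            {(y, s) for y in (2017, 2018)
             for s in ("spring", "summer", "autumn")},
            key=lambda ys: (ys[0], ("spring", "summer", "autumn").index(ys[1])))
        for (sp, plot), hist in histories.items():
            sub = random_captures[(random_captures["species"] == sp)
                                  & (random_captures["plot_id"] == plot)]
            assert hist.sessions == sessions
            for i, ind in enumerate(hist.individual_ids):
                seen = {(int(r.year), r.season)
                        for r in sub[sub["individual_id"] == ind].itertuples()}
                expected = np.array([ys in seen for ys in sessions])
                assert (hist.matrix[i] == expected).all()
        # every record is accounted for
        n_pairs = random_captures.groupby(["species", "plot_id"]).ngroups
        assert len(histories) == n_pairs

    def test_zero_capture_sessions_become_false_columns(self):
        records = pd.DataFrame([make_record(year=2017),
                                make_record(year=2018, ind="SZ-2")])
        hist = build_histories(records)[("SZ", "P01")]
        assert hist.n_sessions == 6  # 2 years x 3 seasons
        assert hist.matrix.sum() == 2

    def test_order_invariance(self, random_captures):
        shuffled = random_captures.sample(frac=1.0, random_state=5)
        a = build_histories(random_captures)
        b = build_histories(shuffled)
        assert a.keys() == b.keys()
        for key in a:
            assert a[key].individual_ids == b[key].individual_ids
            assert (a[key].matrix == b[key].matrix).all()

    def test_conflicting_species_for_one_id_is_named(self):
        records = pd.DataFrame([
            make_record(species="SZ", ind="TAG-9"),
            make_record(species="MZ", ind="TAG-9"),
        ])
        with pytest.raises(ValueError, match="TAG-9"):
            build_histories(records)

    def test_out_of_range_day_and_station_rejected(self):
        with pytest.raises(ValueError, match="day"):
            build_histories(pd.DataFrame([make_record(day=5)]))
        with pytest.raises(ValueError, match="grid"):
            build_histories(pd.DataFrame([make_record(row=7)]))


class TestMnka:
    def test_empty_session_without_bracketing_is_zero(self):
        hist = history_of([[False, True, False]])
        assert mnka(hist, 0) == 0

    def test_caught_plus_bracketed(self):
        # 3 individuals at session 1; one more at sessions 0 and 2 only
        m = np.zeros((4, 3), dtype=bool)
        m[0:3, 1] = True
        m[3, 0] = m[3, 2] = True
        assert mnka(history_of(m), 1) == 4

    def test_session_index_out_of_range(self):
        hist = history_of([[True, False]])
        with pytest.raises(IndexError):
            mnka(hist, 2)

    def test_random_histories_match_exhaustive_oracle(self, rng):
        for _ in range(50):
            m = rng.random((int(rng.integers(1, 15)),
                            int(rng.integers(2, 9)))) < 0.4
            m[m.sum(axis=1) == 0, 0] = True  # every row caught at least once
            hist = history_of(m)
            for t in range(hist.n_sessions):
                assert mnka(hist, t) == mnka_oracle(m, t)

    def test_series_every_session(self):
        m = np.ones((1, 5), dtype=bool)
        assert mnka_series(history_of(m)).tolist() == [1, 1, 1, 1, 1]

    def test_series_bracketing_fills_gaps(self):
        m = np.zeros((1, 5), dtype=bool)
        m[0, 0] = m[0, 4] = True
        assert mnka_series(history_of(m)).tolist() == [1, 1, 1, 1, 1]

    def test_at_least_number_caught_and_endpoints_have_no_b(self, rng):
        for _ in range(20):
            m = rng.random((10, 6)) < 0.5
            m[m.sum(axis=1) == 0, 0] = True
            hist = history_of(m)
            series = mnka_series(hist)
            caught = m.sum(axis=0)
            assert (series >= caught).all()
            assert series[0] == caught[0] and series[-1] == caught[-1]

    @given(st.integers(0, 9), st.integers(0, 5))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_adding_a_capture_never_decreases_mnka(self, i, t):
        rng = np.random.default_rng(42)
        m = rng.random((10, 6)) < 0.3
        m[m.sum(axis=1) == 0, 0] = True
        base = mnka_series(history_of(m))
        m2 = m.copy()
        m2[i, t] = True
        augmented = mnka_series(history_of(m2))
        assert (augmented >= base).all()


class TestDensity:
    def test_zero_count(self):
        assert density(0) == 0.0
        assert log_transform(0) == 0.0

    def test_closed_form(self):
        assert density(9, 1.0) == 9.0
        assert log_transform(9) == pytest.approx(1.0)
        assert density(56, 1.0) == 56.0

    def test_errors(self):
        with pytest.raises(ValueError):
            density(3, 0.0)
        with pytest.raises(ValueError):
            density(-1, 1.0)

    def test_mnka_table_shape(self, random_captures):
        table = mnka_table(build_histories(random_captures))
        assert list(table.columns) == ["year", "season", "plot_id", "species",
                                       "mnka", "density_per_ha"]
        # 6 sessions per (species, plot) pair
        assert (table.groupby(["species", "plot_id"]).size() == 6).all()
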