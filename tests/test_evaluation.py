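"""Station evaluation: NMBF, fire-derived signal isolation, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from firehealth.evaluation import (
    StationSeries,
    composite_series,
    evaluate_stations,
    fire_derived_series,
    nmbf,
    pearson_and_nsd,
    select_fire_influenced,
)
from firehealth.exceptions import StationPlacementError, UndefinedValueError
from firehealth.grids import make_field


def _series(values, start="2014-01"):
    idx = pd.period_range(start=start, periods=len(values), freq="M").to_timestamp()
    return pd.Series(np.asarray(values, dtype=float), index=idx)


def _nmbf_direct(m, o):
    """Independent direct evaluation of the Yu et al. formula."""
    m, o = np.asarray(m, float), np.asarray(o, float)
    if m.mean() >= o.mean():
        return m.sum() / o.sum() - 1.0
    return 1.0 - o.sum() / m.sum()


class TestNMBF:
    def test_identical_series_give_zero(self):
        x = np.array([3.0, 5.0, 9.0])
        assert nmbf(x, x) == 0.0

    def test_factor_two_overestimate(self):
        o = np.array([10.0, 20.0, 30.0])
        assert nmbf(2 * o, o) == pytest.approx(1.0)

    def test_factor_two_underestimate(self):
        o = np.array([10.0, 20.0, 30.0])
        assert nmbf(o / 2, o) == pytest.approx(-1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_formula_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 40)
        m = rng.uniform(0.1, 100, n)
        o = rng.uniform(0.1, 100, n)
        assert nmbf(m, o) == pytest.approx(_nmbf_direct(m, o), abs=1e-12)
        assert nmbf(m, o) == pytest.approx(-nmbf(o, m), abs=1e-12)

    @given(st.floats(0.01, 1000), st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 50, 12)
        o = rng.uniform(0.1, 50, 12)
        assert nmbf(scale * m, scale * o) == pytest.approx(nmbf(m, o), abs=1e-9)

    @given(st.floats(1.0, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_multiplicative_bias_recovered(self, b):
        o = np.array([5.0, 12.0, 40.0, 7.0])
        assert nmbf(b * o, o) == pytest.approx(b - 1.0, rel=1e-12)

    def test_zero_sum_series_rejected(self):
        with pytest.raises(UndefinedValueError):
            nmbf(np.zeros(3), np.ones(3))

    def test_missing_pairs_dropped(self):
        m = np.array([1.0, np.nan, 3.0])
        o = np.array([1.0, 99.0, 3.0])
        assert nmbf(m, o) == 0.0


class TestFireDerivedSeries:
    def test_constant_year_maps_to_zeros(self):
        out = fire_derived_series(_series([40.0] * 12))
        np.testing.assert_allclose(out.values, 0.0)

    def test_hand_subtraction(self):
        out = fire_derived_series(_series([50.0, 30.0, 90.0, 30.0]))
        np.testing.assert_allclose(out.values, [20.0, 0.0, 60.0, 0.0])

    def test_years_processed_independently(self):
        s = _series([10.0, 20.0], start="2013-11")
        s = pd.concat([s, _series([5.0, 50.0], start="2014-01")])
        out = fire_derived_series(s)
        np.testing.assert_allclose(out.values, [0.0, 10.0, 0.0, 45.0])

    def test_single_valid_month_flagged_missing(self):
        s = _series([30.0, np.nan, np.nan], start="2014-01")
        out = fire_derived_series(s)
        assert out.isna().all()

    def test_idempotent(self, rng):
        s = _series(rng.uniform(10, 120, 24))
        once = fire_derived_series(s)
        twice = fire_derived_series(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_nonnegative_output(self, rng):
        out = fire_derived_series(_series(rng.uniform(0, 80, 36)))
        assert (out.dropna() >= 0).all()


class TestPearsonNSD:
    def test_affine_model_perfect_correlation(self):
        o = np.array([1.0, 4.0, 2.0, 8.0])
        met = pearson_and_nsd(3 * o + 2, o)
        assert met.pearson_r == pytest.approx(1.0)
        assert met.r_squared == pytest.approx(1.0)

    def test_anticorrelated(self):
        o = np.array([1.0, 4.0, 2.0, 8.0])
        assert pearson_and_nsd(-o, o).pearson_r == pytest.approx(-1.0)

    def test_nsd_of_doubled_series(self):
        o = np.array([1.0, 4.0, 2.0, 8.0])
        assert pearson_and_nsd(2 * o, o).nsd == pytest.approx(2.0)

    def test_zero_observed_variance_rejected(self):
        with pytest.raises(UndefinedValueError):
            pearson_and_nsd(np.array([1.0, 2.0]), np.array([5.0, 5.0]))


def _make_station(sid, lat, lon, obs, model_all=None):
    obs = np.asarray(obs, dtype=float)
    model_all = obs.copy() if model_all is None else np.asarray(model_all, float)
    idx = pd.period_range("2014-01", periods=len(obs), freq="M").to_timestamp()
    return StationSeries(sid, lat, lon, idx, obs, {"all": model_all})


class TestStationSelection:
    def _fields(self, frac_map):
        lat = 0.5 + np.arange(2)
        lon = 0.5 + np.arange(2)
        allf = make_field(np.full((2, 2), 100.0), lat, lon)
        nofire = make_field(100.0 * (1 - np.asarray(frac_map, float)), lat, lon)
        return allf, nofire

    def test_no_fire_influence_gives_empty_subset(self):
        allf, nofire = self._fields([[0, 0], [0, 0]])
        stations = [_make_station("s1", 0.5, 0.5, np.ones(3))]
        assert select_fire_influenced(allf, nofire, stations, 0.2) == []

    def test_only_station_above_threshold_selected(self):
        allf, nofire = self._fields([[0.5, 0.1], [0.1, 0.1]])
        s_hot = _make_station("hot", 0.5, 0.5, np.ones(3))
        s_cold = _make_station("cold", 1.5, 1.5, np.ones(3))
        out = select_fire_influenced(allf, nofire, [s_hot, s_cold], 0.2)
        assert [s.station_id for s in out] == ["hot"]

    def test_zero_threshold_selects_all(self):
        allf, nofire = self._fields([[0.5, 0.1], [0.1, 0.0]])
        stations = [_make_station("a", 0.5, 0.5, np.ones(3)),
                    _make_station("b", 1.5, 1.5, np.ones(3))]
        assert len(select_fire_influenced(allf, nofire, stations, 0.0)) == 2

    def test_station_outside_grid_reported(self):
        allf, nofire = self._fields([[0, 0], [0, 0]])
        rogue = _make_station("far", 40.0, 40.0, np.ones(3))
        with pytest.raises(StationPlacementError, match="far"):
            select_fire_influenced(allf, nofire, [rogue], 0.2)


class TestComposite:
    def test_composite_is_mean_across_stations(self, rng):
        stations = [
            _make_station(f"s{i}", 0.5, 0.5, rng.uniform(10, 50, 12)) for i in range(4)
        ]
        mod, obs = composite_series(stations)
        expected = np.mean([s.observed for s in stations], axis=0)
        np.testing.assert_allclose(obs.values, expected)

    def test_composite_metrics_differ_from_mean_of_station_metrics(self, rng):
        # regional-average-first and per-station-average metrics are
        # different statistics; document that they need not coincide
        stations = [
            _make_station(
                f"s{i}",
                0.5,
                0.5,
                rng.uniform(10, 50, 12),
                model_all=rng.uniform(10, 50, 12),
            )
            for i in range(5)
        ]
        table = evaluate_stations(stations, fire_derived=False).set_index("station_id")
        per_station_mean = table.drop(index="composite")["nmbf"].mean()
        composite_val = table.loc["composite", "nmbf"]
        assert np.isfinite(per_station_mean) and np.isfinite(composite_val)

    def test_scorecard_has_row_per_station_plus_composite(self, rng):
        stations = [_make_station(f"s{i}", 0.5, 0.5, rng.uniform(10, 50, 12)) for i in range(3)]
        table = evaluate_stations(stations, fire_derived=False)
        assert len(table) == 4
        assert table["station_id"].iloc[-1] == "composite"
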