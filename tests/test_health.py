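"""GEMM/ozone relative risk, attributable burden, subtraction, uncertainty."""

import numpy as np
import pandas as pd
import pytest

from firehealth.exceptions import MissingBaselineError, UndefinedValueError
from firehealth.grids import RegionMask, make_field
from firehealth.health import (
    BurdenResult,
    OzoneERFParameters,
    attributable_fraction,
    fire_attributable_burden,
    gemm_parameters,
    gemm_relative_risk,
    ozone_relative_risk,
    per_capita_rate,
    sample_parameter_draws,
    scenario_burden,
)

GEMM_ROW = {"theta": 0.1, "alpha": 2.0, "mu": 10.0, "nu": 30.0, "cf": 2.4}


def _field(values):
    values = np.asarray(values, dtype=float)
    lat = 0.5 + np.arange(values.shape[0])
    lon = 0.5 + np.arange(values.shape[1])
    return make_field(values, lat, lon)


def _baseline(regions, cause="ncd_lri", age="25+", rate=0.006, daly=0.25, frac=0.6,
              rel_ui=0.0):
    rows = []
    for r in regions:
        rows.append(
            {
                "region": r,
                "cause": cause,
                "age_group": age,
                "mort_rate": rate,
                "mort_lo": rate * (1 - rel_ui),
                "mort_hi": rate * (1 + rel_ui),
                "daly_rate": daly,
                "daly_lo": daly * (1 - rel_ui),
                "daly_hi": daly * (1 + rel_ui),
                "age_fraction": frac,
                "frac_lo": max(frac - rel_ui, 0.0),
                "frac_hi": min(frac + rel_ui, 1.0),
            }
        )
    return pd.DataFrame(rows)


class TestGEMMRelativeRisk:
    def test_rr_is_one_at_or_below_counterfactual(self):
        for c in (0.0, 1.0, 2.4):
            assert gemm_relative_risk(c, GEMM_ROW) == pytest.approx(1.0)

    def test_zero_theta_gives_unit_rr(self):
        row = dict(GEMM_ROW, theta=0.0)
        assert gemm_relative_risk(100.0, row) == pytest.approx(1.0)

    def test_closed_form_oracle_at_z20(self):
        # independent single-expression evaluation at c = 22.4 (z = 20)
        z = 20.0
        expected = np.exp(0.1 * np.log(1 + z / 2.0) / (1 + np.exp(-(z - 10.0) / 30.0)))
        assert gemm_relative_risk(22.4, GEMM_ROW) == pytest.approx(expected, rel=1e-14)

    def test_monotone_nondecreasing_on_dense_grid(self):
        c = np.linspace(0, 300, 10_000)
        for variant in ("ncd_lri", "five_cause"):
            for _, row in gemm_parameters(variant).iterrows():
                rr = gemm_relative_risk(c, row)
                assert np.all(np.diff(rr) >= -1e-12)
                assert np.all(rr >= 1.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            gemm_relative_risk(-1.0, GEMM_ROW)


class TestOzoneRelativeRisk:
    def test_unit_rr_at_or_below_tmrel(self):
        p = OzoneERFParameters(tmrel=26.7)
        assert ozone_relative_risk(26.7, p) == pytest.approx(1.0)
        assert ozone_relative_risk(5.0, p) == pytest.approx(1.0)

    def test_single_increment(self):
        p = OzoneERFParameters(rr_per_10ppb=1.12, tmrel=30.0)
        assert ozone_relative_risk(40.0, p) == pytest.approx(1.12)

    def test_two_increments_compound(self):
        p = OzoneERFParameters(rr_per_10ppb=1.12, tmrel=30.0)
        assert ozone_relative_risk(50.0, p) == pytest.approx(1.2544, rel=1e-12)


class TestAttributableFraction:
    @pytest.mark.parametrize("rr, af", [(1.0, 0.0), (2.0, 0.5), (1.25, 0.2)])
    def test_values(self, rr, af):
        assert attributable_fraction(rr) == pytest.approx(af)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(0.0)

    def test_rr_below_one_warns_and_is_negative(self):
        with pytest.warns(UserWarning):
            assert attributable_fraction(0.8) < 0

    def test_af_bounded_on_nonnegative_field(self):
        c = np.linspace(0, 500, 1000)
        af = attributable_fraction(gemm_relative_risk(c, GEMM_ROW))
        assert np.all((af >= 0) & (af < 1))


class TestScenarioBurden:
    def test_counterfactual_field_gives_zero_burden(self):
        field = _field(np.full((3, 3), 2.4))
        pop = _field(np.full((3, 3), 1e5))
        res = scenario_burden(field, pop, _baseline(["domain"]), gemm_parameters(), "PM2.5")
        assert res.central("mortality") == pytest.approx(0.0, abs=1e-9)

    def test_rr_two_halves_baseline_burden(self):
        # ozone route: exposure one doubling-increment above threshold -> RR 2, AF 0.5
        p = OzoneERFParameters(rr_per_10ppb=2.0, rr_ci=(2.0, 2.0), tmrel=30.0, cause="resp")
        field = _field(np.full((2, 2), 40.0))
        pop = _field(np.full((2, 2), 1.0))
        base = _baseline(["domain"], cause="resp", rate=250.0, frac=1.0)
        # rate * frac * pop = 250 * 1 * 4 = 1000 baseline-scale deaths
        res = scenario_burden(field, pop, base, p, kind="O3")
        assert res.central("mortality") == pytest.approx(500.0)

    def test_burden_linear_in_population(self):
        field = _field(np.full((3, 3), 35.0))
        pop = _field(np.full((3, 3), 1e4))
        base = _baseline(["domain"])
        r1 = scenario_burden(field, pop, base, gemm_parameters(), "PM2.5")
        r2 = scenario_burden(field, 2.0 * pop, base, gemm_parameters(), "PM2.5")
        assert r2.central("mortality") == pytest.approx(2 * r1.central("mortality"), rel=1e-12)

    def test_missing_baseline_region_is_named(self):
        field = _field(np.full((2, 2), 30.0))
        pop = _field(np.ones((2, 2)))
        lat, lon = field.coords["lat"].values, field.coords["lon"].values
        masks = [RegionMask.from_box("orphan", lat, lon)]
        with pytest.raises(MissingBaselineError, match="orphan"):
            scenario_burden(field, pop, _baseline(["elsewhere"]), gemm_parameters(),
                            "PM2.5", masks=masks)

    def test_regional_additivity_over_partition(self):
        vals = np.linspace(5, 60, 16).reshape(4, 4)
        field = _field(vals)
        pop = _field(np.full((4, 4), 2e4))
        lat, lon = field.coords["lat"].values, field.coords["lon"].values
        west = RegionMask.from_box("west", lat, lon, lon_max=2.0)
        east = RegionMask.from_box("east", lat, lon, lon_min=2.0)
        whole = RegionMask.from_box("whole", lat, lon)
        base = _baseline(["west", "east", "whole"])
        parts = scenario_burden(field, pop, base, gemm_parameters(), "PM2.5",
                                masks=[west, east])
        total = scenario_burden(field, pop, base, gemm_parameters(), "PM2.5", masks=[whole])
        assert parts.central("mortality") == pytest.approx(
            total.central("mortality"), rel=1e-12
        )

    def test_concave_response_burden_reduction_below_exposure_reduction(self):
        # homogeneous population: percentage burden reduction must not
        # exceed percentage exposure reduction for the concave GEMM RR
        all_field = _field(np.full((3, 3), 40.0))
        nofire_field = _field(np.full((3, 3), 24.0))  # 40% exposure reduction
        pop = _field(np.full((3, 3), 1e5))
        base = _baseline(["domain"])
        b_all = scenario_burden(all_field, pop, base, gemm_parameters(), "PM2.5")
        b_no = scenario_burden(nofire_field, pop, base, gemm_parameters(), "PM2.5")
        burden_red = 100 * (1 - b_no.central("mortality") / b_all.central("mortality"))
        assert burden_red <= 40.0


class TestSubtraction:
    def _result(self, values, regions=("a", "b")):
        table = pd.DataFrame(
            {
                "region": list(regions),
                "cause": "ncd_lri",
                "age_group": "25+",
                "mortality": values,
                "daly": [10 * v for v in values],
            }
        )
        return BurdenResult(table=table)

    def test_identical_scenarios_give_zero(self):
        a = self._result([50.0, 70.0])
        fire = fire_attributable_burden(a, self._result([50.0, 70.0]))
        assert fire.central("mortality") == pytest.approx(0.0)

    def test_plain_difference(self):
        fire = fire_attributable_burden(self._result([120.0, 0.0]), self._result([100.0, 0.0]))
        assert fire.central("mortality", region="a") == pytest.approx(20.0)

    def test_sum_over_strata_commutes_with_subtraction(self):
        a = self._result([120.0, 80.0])
        n = self._result([100.0, 50.0])
        fire = fire_attributable_burden(a, n)
        assert fire.central("mortality") == pytest.approx(
            a.central("mortality") - n.central("mortality")
        )

    def test_stratification_mismatch_raises(self):
        with pytest.raises(UndefinedValueError):
            fire_attributable_burden(self._result([1.0, 2.0]),
                                     self._result([1.0, 2.0], regions=("a", "c")))


class TestUncertainty:
    def _setup(self, rel_ui, theta_se=None, n_draws=200, seed=11):
        gemm = gemm_parameters()
        if theta_se is not None:
            gemm["theta_se"] = theta_se
        base = _baseline(["domain"], rel_ui=rel_ui)
        field = _field(np.full((3, 3), 45.0))
        pop = _field(np.full((3, 3), 1e5))
        draws = sample_parameter_draws(base, gemm, None, n_draws=n_draws, seed=seed)
        res = scenario_burden(field, pop, base, gemm, "PM2.5", draws=draws)
        return res

    def test_zero_uncertainty_collapses_to_central(self):
        res = self._setup(rel_ui=0.0, theta_se=0.0)
        lo, hi = res.ui("mortality")
        assert lo == pytest.approx(res.central("mortality"), rel=1e-12)
        assert hi == pytest.approx(res.central("mortality"), rel=1e-12)

    def test_same_seed_is_bit_reproducible(self):
        a = self._setup(rel_ui=0.1)
        b = self._setup(rel_ui=0.1)
        np.testing.assert_array_equal(a.draws["mortality"], b.draws["mortality"])

    def test_interval_brackets_central(self):
        res = self._setup(rel_ui=0.1, n_draws=500)
        lo, hi = res.ui("mortality")
        assert lo <= res.central("mortality") <= hi

    def test_nonpositive_draw_count_rejected(self):
        from firehealth.exceptions import ConfigurationError

        with pytest.raises(ConfigurationError):
            sample_parameter_draws(_baseline(["domain"]), gemm_parameters(), None, n_draws=0)


class TestPerCapita:
    def test_rate_per_100k(self):
        assert per_capita_rate(25.0, 100_000.0) == pytest.approx(25.0)
        assert per_capita_rate(0.0, 1e6) == 0.0

    def test_doubling_population_halves_rate(self):
        assert per_capita_rate(40.0, 2e5) == pytest.approx(per_capita_rate(40.0, 1e5) / 2)

    def test_zero_population_rejected(self):
        with pytest.raises(UndefinedValueError):
            per_capita_rate(10.0, 0.0)
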