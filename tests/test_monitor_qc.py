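"""Monitor QC: validity filter, completeness screen, MDL handling, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from segmetals import monitor_qc
from segmetals.errors import ConfigurationError, InsufficientDataError, UnitError

from conftest import make_daily_records


class TestFilterValid:
    def test_drops_invalid_rows_preserving_order(self):
        rec = make_daily_records(10)
        rec.loc[[1, 4, 7], "valid"] = False
        out = monitor_qc.filter_valid(rec)
        assert len(out) == 7
        assert list(out.index) == [0, 2, 3, 5, 6, 8, 9]

    def test_identity_when_all_valid(self):
        rec = make_daily_records(15)
        pd.testing.assert_frame_equal(monitor_qc.filter_valid(rec), rec)

    def test_counts_on_constructed_mixed_fixture(self):
        rec = make_daily_records(121)
        rec.loc[rec.index[:11], "valid"] = False
        assert len(monitor_qc.filter_valid(rec)) == 110

    def test_missing_concentration_dropped_even_if_valid(self):
        rec = make_daily_records(5)
        rec.loc[2, "concentration"] = np.nan
        assert len(monitor_qc.filter_valid(rec)) == 4


class TestCompletenessScreen:
    @pytest.mark.parametrize("n_samples, retained", [
        (61, True),   # 61/121 ~ 0.504 > 0.5
        (60, False),  # 60/121 ~ 0.496
        (121, True),
        (1, False),
    ])
    def test_strict_majority_rule(self, n_samples, retained):
        rec = make_daily_records(n_samples)
        out = monitor_qc.annual_monitor_mean(rec, 2019)
        assert (len(out) == 1) is retained

    def test_exactly_half_is_rejected(self):
        rec = make_daily_records(61)
        out = monitor_qc.annual_monitor_mean(rec, 2019, expected_n=122)
        assert len(out) == 0  # 61/122 == 0.5 exactly: "greater than 50%"

    def test_mean_of_constant_days_is_exact(self):
        rec = make_daily_records(100, concentration=3.25)
        out = monitor_qc.annual_monitor_mean(rec, 2019)
        assert out["mean_concentration"].iloc[0] == 3.25
        assert out["n_samples"].iloc[0] == 100

    def test_absent_year_returns_empty_not_error(self):
        out = monitor_qc.annual_monitor_mean(make_daily_records(50), 1999)
        assert len(out) == 0

    def test_per_monitor_expected_n_override(self):
        rec = make_daily_records(31)  # a monitor active half the year
        out = monitor_qc.annual_monitor_mean(rec, 2019, expected_n={"M1": 61})
        assert len(out) == 1

    @given(n_drop=st.integers(min_value=1, max_value=60))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_filter_is_monotone_in_row_removal(self, n_drop):
        """Removing rows never turns a rejected monitor-year into retained."""
        rec = make_daily_records(60)  # already rejected
        out = monitor_qc.annual_monitor_mean(rec.iloc[n_drop:], 2019)
        assert len(out) == 0


class TestMdlImputation:
    def test_below_mdl_replaced_by_mdl_over_sqrt2(self):
        rec = make_daily_records(3, concentration=[0.5, 1.5, 1.0], mdl=1.0)
        out = monitor_qc.impute_below_mdl(rec, "mdl_over_sqrt2")
        assert out["concentration"].iloc[0] == pytest.approx(0.70711, abs=5e-6)
        assert out["concentration"].iloc[1] == 1.5    # above MDL untouched
        assert out["concentration"].iloc[2] == 1.0    # at MDL untouched

    def test_keep_strategy_is_identity(self):
        rec = make_daily_records(10, concentration=0.01, mdl=1.0)
        out = monitor_qc.impute_below_mdl(rec, "keep")
        pd.testing.assert_frame_equal(out, rec)

    def test_unknown_strategy_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            monitor_qc.impute_below_mdl(make_daily_records(2), "zero_out")

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_imputation_direction_and_no_op_cases(self, seed):
        rng = np.random.default_rng(seed)
        # draws at or below MDL/sqrt2: substitution can only raise the mean
        low = rng.uniform(0.0, 1.0 / np.sqrt(2), 40)
        rec = make_daily_records(40, concentration=low, mdl=1.0)
        out = monitor_qc.impute_below_mdl(rec, "mdl_over_sqrt2")
        assert out["concentration"].mean() >= rec["concentration"].mean() - 1e-12
        # no below-MDL rows: table unaltered
        high = rng.uniform(1.0, 3.0, 40)
        rec2 = make_daily_records(40, concentration=high, mdl=1.0)
        pd.testing.assert_frame_equal(
            monitor_qc.impute_below_mdl(rec2, "mdl_over_sqrt2"), rec2)


class TestCountyAggregation:
    def _monitor_means(self, rows):
        return pd.DataFrame([
            {"monitor_id": m, "county_id": c, "component": comp, "year": 2019,
             "mean_concentration": v, "n_samples": 100, "expected_n": 121,
             "completeness": 100 / 121, "urban": True, "region": "South",
             "latitude": 35.0, "longitude": -90.0}
            for (m, c, comp, v) in rows
        ])

    def test_single_monitor_passthrough_and_midpoint(self):
        means = self._monitor_means([
            ("M1", "00001", "Pb", 2.0), ("M2", "00001", "Pb", 4.0),
            ("M3", "00002", "Pb", 7.5),
        ])
        county = monitor_qc.county_annual_exposure(means)
        by = county.set_index("county_id")
        assert by.loc["00001", "mean_concentration"] == 3.0  # unweighted mean
        assert by.loc["00001", "n_monitors"] == 2
        assert by.loc["00002", "mean_concentration"] == 7.5

    def test_mass_proportion_unit_harmonisation(self):
        # Pb 3 ng/m3 over PM2.5 10 ug/m3 -> 3e-4 by mass
        means = self._monitor_means([
            ("M1", "00001", "Pb", 3.0), ("M1", "00001", "PM25", 10.0),
        ])
        county = monitor_qc.county_annual_exposure(means)
        pb = county.query("component == 'Pb'")
        assert pb["mass_proportion"].iloc[0] == pytest.approx(3e-4, rel=1e-12)
        pm = county.query("component == 'PM25'")
        assert pm["mass_proportion"].isna().all()

    def test_mass_proportion_absent_without_pm25(self):
        means = self._monitor_means([("M1", "00001", "Pb", 3.0)])
        county = monitor_qc.county_annual_exposure(means)
        assert county["mass_proportion"].isna().all()

    def test_unknown_component_is_unit_error(self):
        means = self._monitor_means([("M1", "00001", "Xx", 3.0)])
        with pytest.raises(UnitError):
            monitor_qc.county_annual_exposure(means)

    def test_mass_proportion_times_pm25_recovers_metal_mean(self):
        rng = np.random.default_rng(99)
        rows = []
        for i in range(10):
            cid = f"{i:05d}"
            rows += [("M1", cid, "Pb", rng.uniform(0.5, 5)),
                     ("M1", cid, "PM25", rng.uniform(4, 20))]
        county = monitor_qc.county_annual_exposure(self._monitor_means(rows))
        pb = county.query("component == 'Pb'").set_index("county_id")
        pm = county.query("component == 'PM25'").set_index("county_id")
        recovered = (pb["mass_proportion"]
                     * pm["mean_concentration"] * monitor_qc.UG_TO_NG)
        np.testing.assert_allclose(recovered, pb["mean_concentration"],
                                   rtol=1e-12)


class TestUrbanRatio:
    def _county_table(self, urban_vals, rural_vals, component="Pb"):
        rows = []
        for i, v in enumerate(urban_vals):
            rows.append({"county_id": f"u{i}", "component": component,
                         "year": 2019, "mean_concentration": v,
                         "mass_proportion": np.nan, "urban": True})
        for i, v in enumerate(rural_vals):
            rows.append({"county_id": f"r{i}", "component": component,
                         "year": 2019, "mean_concentration": v,
                         "mass_proportion": np.nan, "urban": False})
        return pd.DataFrame(rows)

    def test_point_estimate_is_ratio_of_stratum_means(self):
        table = self._county_table([4, 6], [1, 3])
        ratio, lo, hi = monitor_qc.urban_nonurban_ratio(
            table, "Pb", n_boot=500, seed=1)
        assert ratio == pytest.approx(2.5)
        assert lo <= ratio <= hi

    def test_identical_strata_give_ratio_one(self):
        table = self._county_table([2, 3, 4], [2, 3, 4])
        ratio, lo, hi = monitor_qc.urban_nonurban_ratio(
            table, "Pb", n_boot=2000, seed=2)
        assert ratio == 1.0
        assert lo <= 1.0 <= hi

    def test_singleton_strata_degenerate_ci(self):
        table = self._county_table([5.0], [2.0])
        ratio, lo, hi = monitor_qc.urban_nonurban_ratio(
            table, "Pb", n_boot=1000, seed=3)
        assert ratio == lo == hi == 2.5

    def test_empty_stratum_is_insufficient_data(self):
        table = self._county_table([5.0], [])
        with pytest.raises(InsufficientDataError, match="nonurban"):
            monitor_qc.urban_nonurban_ratio(table, "Pb", seed=4)
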