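"""Trend statistics, shares, and full-annual-dataset export."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2obudget.records import EmissionEstimate, InventoryTable
from n2obudget.trends import (
    contribution_pct,
    decadal_change_pct,
    export_fan,
    linear_trend,
    mann_kendall,
    mann_kendall_s_bruteforce,
    read_fan,
    sector_share,
)


class TestDecadalChange:
    def test_published_total_changes(self, table1):
        totals = pd.Series(table1.printed_total)
        assert decadal_change_pct(totals, 1980, 1990) == 38.2
        assert decadal_change_pct(totals, 1990, 2000) == 15.3
        assert decadal_change_pct(totals, 2000, 2010) == 31.5
        assert decadal_change_pct(totals, 2010, 2020) == 23.1

    def test_constant_series_is_zero(self):
        s = pd.Series({1980: 5.0, 1990: 5.0})
        assert decadal_change_pct(s, 1980, 1990) == 0.0

    def test_zero_start_rejected(self):
        with pytest.raises(ZeroDivisionError):
            decadal_change_pct(pd.Series({1980: 0.0, 1990: 1.0}), 1980, 1990)

    def test_missing_year_rejected(self):
        with pytest.raises(KeyError):
            decadal_change_pct(pd.Series({1980: 1.0}), 1980, 1990)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_to_uniform_rescaling(self, scale):
        s = pd.Series({1980: 10.0, 1990: 14.0})
        assert decadal_change_pct(s * scale, 1980, 1990) == (
            decadal_change_pct(s, 1980, 1990)
        )


class TestContribution:
    def test_published_agriculture_contribution(self, table1):
        ag = pd.Series(table1.printed_subtotals["agriculture"])
        total = pd.Series(table1.printed_total)
        pct, share = contribution_pct(ag, total, 1980, 1990)
        assert pct == 25.5
        assert share == 66.7

    def test_component_equal_to_total_has_full_share(self):
        t = pd.Series({1980: 10.0, 1990: 16.0})
        pct, share = contribution_pct(t, t, 1980, 1990)
        assert share == 100.0

    def test_zero_change_component(self):
        c = pd.Series({1980: 3.0, 1990: 3.0})
        t = pd.Series({1980: 10.0, 1990: 16.0})
        assert contribution_pct(c, t, 1980, 1990) == (0.0, 0.0)

    def test_flat_total_rejected(self):
        c = pd.Series({1980: 1.0, 1990: 2.0})
        t = pd.Series({1980: 10.0, 1990: 10.0})
        with pytest.raises(ZeroDivisionError):
            contribution_pct(c, t, 1980, 1990)


class TestSectorShare:
    def test_published_2020_anthropogenic_shares(self, table1):
        shares = sector_share(table1.table, 2020, basis="anthropogenic")
        assert shares["agriculture"] == 49.3
        assert shares["industry"] == 26.4
        assert shares["energy"] == 17.5
        assert shares["waste"] == 6.7

    def test_shares_sum_to_100(self, table1):
        for basis in ("anthropogenic", "total"):
            shares = sector_share(table1.table, 2020, basis=basis)
            assert abs(round(sum(shares.values()), 1) - 100.0) <= 0.1

    def test_single_sector_table(self):
        t = InventoryTable.from_estimates([
            EmissionEstimate(year=2020, province=None, sector="waste",
                             category="Wastewater treatment and discharge",
                             n2o_n_gg=5.0)
        ])
        assert sector_share(t, 2020) == {"waste": 100.0}

    def test_missing_sector_for_year_rejected(self, table1):
        df = table1.table.df
        partial = InventoryTable(
            pd.concat([
                df[df.year == 2020],
                df[(df.year == 2010) & (df.sector == "energy")],
            ])
        )
        with pytest.raises(KeyError, match="no rows for year 2010"):
            sector_share(partial, 2010)

    def test_invalid_basis(self, table1):
        with pytest.raises(ValueError):
            sector_share(table1.table, 2020, basis="net")


class TestLinearTrend:
    def test_noise_free_line(self):
        years = np.arange(1980, 2021)
        s = pd.Series(2.0 * (years - 1980), index=years)
        slope, accumulated = linear_trend(s)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert accumulated == pytest.approx(82.0, abs=1e-9)

    def test_constant_series(self):
        s = pd.Series(5.0, index=np.arange(2000, 2010))
        assert linear_trend(s)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_oracle(self):
        # closed-form OLS on 5 points computed by hand:
        # x=[0..4], y=[1,3,2,5,4]: slope = sum((x-2)(y-3))/sum((x-2)^2) = 0.8
        s = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0], index=[2000, 2001, 2002, 2003, 2004])
        assert linear_trend(s)[0] == pytest.approx(0.8, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            linear_trend(pd.Series({2000: 1.0, 2001: 2.0}))


class TestMannKendall:
    def test_strictly_increasing(self):
        s = pd.Series(np.arange(41.0), index=np.arange(1980, 2021))
        res = mann_kendall(s)
        assert res.tau == pytest.approx(1.0)
        assert res.p < 0.001
        assert res.increasing

    def test_strictly_decreasing(self):
        s = pd.Series(-np.arange(41.0), index=np.arange(1980, 2021))
        res = mann_kendall(s)
        assert res.tau == pytest.approx(-1.0)
        assert not res.increasing

    def test_four_point_example_brute_force(self):
        s = pd.Series([1.0, 3.0, 2.0, 4.0], index=[1, 2, 3, 4])
        assert mann_kendall(s).s == 4
        assert mann_kendall_s_bruteforce(s) == 4

    def test_all_identical_series(self):
        s = pd.Series(3.0, index=np.arange(2000, 2010))
        res = mann_kendall(s)
        assert res.tau == 0.0
        assert res.p == 1.0
        assert not res.increasing

    def test_matches_brute_force_exhaustively_small_n(self):
        """Normal-approximation path S equals explicit pair counting for
        every permutation-with-ties pattern up to n=6 and random n<=10."""
        for n in (4, 5, 6):
            for vals in itertools.product((0.0, 1.0, 2.0), repeat=n):
                s = pd.Series(vals, index=range(n))
                assert mann_kendall(s).s == mann_kendall_s_bruteforce(s)
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 11))
            s = pd.Series(rng.integers(0, 5, n).astype(float), index=range(n))
            assert mann_kendall(s).s == mann_kendall_s_bruteforce(s)


class TestExport:
    def test_round_trip(self, table1, tmp_path):
        paths = export_fan(table1.table, tmp_path)
        again = read_fan(paths["inventory"])
        expected = table1.table.df.reset_index(drop=True).copy()
        # CSV has no notion of None vs NaN for national-level rows
        for col in ("province", "region"):
            expected[col] = expected[col].where(expected[col].notna(), np.nan)
        pd.testing.assert_frame_equal(
            again.df.reset_index(drop=True), expected, check_dtype=False,
        )

    def test_fixture_total_reconstructs(self, table1, tmp_path):
        paths = export_fan(table1.table, tmp_path)
        again = read_fan(paths["inventory"])
        # subtotals from printed-rounded line items re-aggregate within 0.2
        assert again.total_n2o_gg(year=2020) == pytest.approx(2295.0, abs=0.2)

    def test_empty_table_writes_header_only(self, tmp_path):
        paths = export_fan(InventoryTable.empty(), tmp_path)
        df = pd.read_csv(paths["inventory"])
        assert len(df) == 0 and "category" in df.columns

    def test_natural_grid_written(self, table1, tmp_path, small_grid,
                                  small_forcings):
        import xarray as xr

        from n2obudget.natural_soil import ModelParams, simulate_grid

        ds, _nat = simulate_grid(small_grid, small_forcings, ModelParams(),
                                 years=[1980, 1981], spinup=1)
        paths = export_fan(table1.table, tmp_path, natural_grid=ds)
        back = xr.open_dataset(paths["natural"])
        assert back["n2o_flux"].shape == ds["n2o_flux"].shape
        back.close()
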