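"""Soil process model: conservation, pathway structure, drivers, gridding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2obudget.natural_soil import (
    Forcing,
    GridSpec,
    LC_FOREST,
    LC_GRASSLAND,
    ModelParams,
    SoilState,
    factorial_experiments,
    initial_state,
    national_series,
    run_single_cell,
    simulate_grid,
    step,
    step_two_pathway,
)


def forcing(year=2000, t=12.0, w=0.6, ndep=2.0, co2=370.0, cover="forest"):
    return Forcing(year=year, temp_c=t, wfps=w, ndep=ndep, co2=co2,
                   landcover=cover)


def forcing_seq(years=range(1980, 2021), **kw):
    return [forcing(year=y, **kw) for y in years]


class TestStep:
    def test_no_substrate_no_flux(self):
        state = SoilState(nh4=0.0, no3=0.0, son=0.0)
        _new, fl = step(state, forcing(ndep=0.0), ModelParams())
        assert fl["n2o_total"] == 0.0

    def test_invalid_params_rejected_before_stepping(self):
        with pytest.raises(ValueError, match="yield|lie in"):
            step(SoilState(), forcing(), ModelParams(y_auto_nit=1.5))

    def test_invalid_forcing_rejected(self):
        with pytest.raises(ValueError, match="WFPS"):
            step(SoilState(), forcing(w=1.4), ModelParams())

    def test_mass_balance_closes(self):
        p = ModelParams()
        state = initial_state("forest")
        f = forcing()
        new, fl = step(state, f, p)
        budget = (
            f.ndep
            - (1 - p.litter_frac) * fl["uptake"]
            - fl["n2o_total"]
            - fl["n2_loss"]
        )
        assert new.total_n() - state.total_n() == pytest.approx(budget, abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(
        t=st.floats(-15.0, 35.0),
        w=st.floats(0.0, 1.0),
        ndep=st.floats(0.0, 10.0),
        co2=st.floats(200.0, 800.0),
        nh4=st.floats(0.0, 50.0),
        no3=st.floats(0.0, 50.0),
        son=st.floats(0.0, 1000.0),
    )
    def test_pools_and_fluxes_nonnegative_and_balanced(
        self, t, w, ndep, co2, nh4, no3, son
    ):
        p = ModelParams()
        state = SoilState(nh4=nh4, no3=no3, son=son)
        f = forcing(t=t, w=w, ndep=ndep, co2=co2)
        new, fl = step(state, f, p)
        for name in ("nh4", "no3", "son"):
            assert getattr(new, name) >= 0
        for v in fl.values():
            assert v >= 0
        budget = (
            ndep - (1 - p.litter_frac) * fl["uptake"]
            - fl["n2o_total"] - fl["n2_loss"]
        )
        assert new.total_n() - state.total_n() == pytest.approx(budget, abs=1e-9)


class TestPathways:
    def test_two_pathway_equals_zeroed_yields_bitwise(self):
        p = ModelParams()
        state = initial_state("forest")
        f = forcing()
        zeroed = p.two_pathway()
        s1, f1 = step(state, f, zeroed)
        s2, f2 = step_two_pathway(state, f, p)
        for k in f1:
            assert np.asarray(f1[k] == f2[k]).all()
        assert s1.nh4 == s2.nh4 and s1.no3 == s2.no3 and s1.son == s2.son

    def test_two_pathway_extra_yields_inactive(self):
        _s, fl = step_two_pathway(initial_state("forest"), forcing(),
                                  ModelParams())
        assert fl["n2o_heterotrophic_nitrification"] == 0.0
        assert fl["n2o_nitrifier_denitrification"] == 0.0
        assert fl["n2o_total"] > 0.0

    def test_zero_substrate_zero_flux_two_pathway(self):
        _s, fl = step_two_pathway(
            SoilState(nh4=0, no3=0, son=0), forcing(ndep=0), ModelParams()
        )
        assert fl["n2o_total"] == 0.0


class TestDrivers:
    def test_more_deposition_more_n2o(self):
        p = ModelParams()
        base = run_single_cell(forcing_seq(ndep=2.0), p, spinup=30).sum()
        high = run_single_cell(forcing_seq(ndep=4.0), p, spinup=30).sum()
        assert high > base

    def test_co2_ramp_suppresses_n2o(self):
        p = ModelParams()
        years = list(range(1980, 2021))
        held = run_single_cell(forcing_seq(years), p, spinup=30).sum()
        ramped = [forcing(year=y, co2=340.0 + 1.8 * (y - 1980)) for y in years]
        assert run_single_cell(ramped, p, spinup=30).sum() < held

    def test_co2_neutral_when_beta_zero(self):
        p = ModelParams(beta=0.0)
        years = list(range(1980, 2021))
        held = run_single_cell(forcing_seq(years, co2=340.0), p, spinup=30)
        ramped = [forcing(year=y, co2=340.0 + 1.8 * (y - 1980)) for y in years]
        assert np.allclose(run_single_cell(ramped, p, spinup=30), held)

    def test_warming_increases_n2o(self):
        p = ModelParams()
        cool = run_single_cell(forcing_seq(t=10.0), p, spinup=30).sum()
        warm = run_single_cell(forcing_seq(t=13.0), p, spinup=30).sum()
        assert warm > cool


class TestGrid:
    def test_single_cell_area_arithmetic(self):
        lc = np.array([[LC_FOREST]])
        grid = GridSpec(landcover=lc)
        assert grid.cell_area_m2 == pytest.approx(6.25e8)

    def test_empty_mask_gives_zero(self, small_forcings):
        lc = np.zeros((12, 12), dtype=int)
        grid = GridSpec(landcover=lc)
        _ds, nat = simulate_grid(grid, small_forcings, ModelParams(), spinup=2)
        assert (nat["n2o_gg"] == 0).all()

    def test_disjoint_masks_add(self, small_forcings, small_grid):
        p = ModelParams()
        lc = np.asarray(small_grid.landcover)
        only_forest = GridSpec(landcover=np.where(lc == LC_FOREST, lc, 0))
        only_grass = GridSpec(landcover=np.where(lc == LC_GRASSLAND, lc, 0))
        _d, full = simulate_grid(small_grid, small_forcings, p, spinup=3)
        _d, nf = simulate_grid(only_forest, small_forcings, p, spinup=3)
        _d, ng = simulate_grid(only_grass, small_forcings, p, spinup=3)
        total = national_series(full)
        parts = national_series(nf) + national_series(ng)
        assert np.allclose(total, parts, rtol=1e-12)

    def test_missing_forcing_years_listed(self, small_forcings, small_grid):
        with pytest.raises(ValueError, match="2031"):
            simulate_grid(small_grid, small_forcings, ModelParams(),
                          years=[2019, 2031])

    def test_deterministic_given_inputs(self, small_forcings, small_grid):
        p = ModelParams()
        a = simulate_grid(small_grid, small_forcings, p, spinup=3)[1]
        b = simulate_grid(small_grid, small_forcings, p, spinup=3)[1]
        assert np.array_equal(a["n2o_gg"].to_numpy(), b["n2o_gg"].to_numpy())

    def test_forest_and_grassland_reported_separately(
        self, small_forcings, small_grid
    ):
        _ds, nat = simulate_grid(small_grid, small_forcings, ModelParams(),
                                 spinup=3)
        assert set(nat["landcover"]) == {"forest", "grassland"}


class TestFactorial:
    def test_constant_drivers_give_zero_contributions(self, small_grid):
        import xarray as xr

        years = np.arange(2000, 2011)
        ny, nx = small_grid.shape
        ds = xr.Dataset(
            {
                "t": (("year", "y", "x"), np.full((len(years), ny, nx), 11.0)),
                "wfps": (("year", "y", "x"), np.full((len(years), ny, nx), 0.6)),
                "ndep": (("year", "y", "x"), np.full((len(years), ny, nx), 2.0)),
                "co2": (("year",), np.full(len(years), 370.0)),
            },
            coords={"year": years},
        )
        res = factorial_experiments(small_grid, ds, ModelParams(), spinup=5)
        for v in res["contributions_gg"].values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_single_varying_driver_captures_total_change(self, small_grid):
        import xarray as xr

        years = np.arange(2000, 2021)
        ny, nx = small_grid.shape
        ndep = 1.5 + 0.05 * (years - years[0])
        ds = xr.Dataset(
            {
                "t": (("year", "y", "x"), np.full((len(years), ny, nx), 11.0)),
                "wfps": (("year", "y", "x"), np.full((len(years), ny, nx), 0.6)),
                "ndep": (("year", "y", "x"),
                         np.broadcast_to(ndep[:, None, None],
                                         (len(years), ny, nx)).copy()),
                "co2": (("year",), np.full(len(years), 370.0)),
            },
            coords={"year": years},
        )
        res = factorial_experiments(small_grid, ds, ModelParams(), spinup=400,
                                    window_years=len(years))
        c = res["contributions_gg"]
        assert c["NDEP"] > 0
        assert c["CO2"] == pytest.approx(0.0, abs=1e-9)
        assert c["CLIM"] == pytest.approx(0.0, abs=1e-9)
        assert c["NDEP"] == pytest.approx(res["total_change_gg"], rel=0.05)

    def test_realistic_forcing_signs(self, small_grid, small_forcings):
        res = factorial_experiments(small_grid, small_forcings, ModelParams(),
                                    spinup=10)
        c = res["contributions_gg"]
        assert c["NDEP"] > 0
        assert c["CO2"] < 0
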