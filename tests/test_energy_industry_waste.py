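"""Energy, industry, and waste sector engines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2obudget import energy as en
from n2obudget import industry as ind
from n2obudget import waste as ws
from n2obudget.records import InventoryTable
from n2obudget.units import UnitError


def fuel(quantity, unit="TJ", ncv=None, category="Electricity generation"):
    return en.FuelRecord(
        year=2010, province="Hebei", category=category, fuel="coal",
        quantity=quantity, unit=unit, ncv=ncv,
    )


class TestEnergy:
    def test_tj_hand_arithmetic(self):
        # 1000 TJ x 1.5 kg/TJ = 1.5 t N2O
        est = en.combustion_emission(fuel(1000.0), 1.5)
        assert est.n2o_gg == pytest.approx(1.5e-3, rel=1e-12)

    def test_mass_times_ncv(self):
        # 100 kt x 0.0209 TJ/t x 1.5 kg/TJ = 3.135 t N2O
        est = en.combustion_emission(fuel(100.0, "kt", ncv=0.0209), 1.5)
        assert est.n2o_gg == pytest.approx(3.135e-3, rel=1e-9)

    def test_zero_quantity(self):
        assert en.combustion_emission(fuel(0.0), 1.5).n2o_n_gg == 0.0

    def test_missing_ncv_rejected(self):
        with pytest.raises(UnitError, match="calorific"):
            en.combustion_emission(fuel(100.0, "kt"), 1.5)

    def test_category_set_is_closed(self):
        with pytest.raises(ValueError, match="closed"):
            fuel(1.0, category="Space heating")

    @settings(derandomize=True, max_examples=30)
    @given(mass_kt=st.floats(0.1, 1e4), ncv=st.floats(1e-3, 0.05))
    def test_tj_vs_mass_ncv_equivalence(self, mass_kt, ncv):
        tj = mass_kt * 1e3 * ncv
        a = en.combustion_emission(fuel(tj), 1.5).n2o_n_gg
        b = en.combustion_emission(fuel(mass_kt, "kt", ncv=ncv), 1.5).n2o_n_gg
        assert b == pytest.approx(a, rel=1e-9)

    def test_fugitive_linearity(self):
        cat = "Fugitive emissions from fuels"
        one = en.fugitive_emission(fuel(10.0, category=cat), 0.05)
        two = en.fugitive_emission(fuel(20.0, category=cat), 0.05)
        assert one.n2o_gg == pytest.approx(0.5e-6, rel=1e-12)  # 0.5 kg
        assert two.n2o_n_gg == pytest.approx(2 * one.n2o_n_gg, rel=1e-12)

    def test_subtotal_is_sum_of_11_categories(self, rng):
        ests = [
            en.combustion_emission(fuel(float(rng.uniform(0, 1e4)), category=c), 1.5)
            if c != "Fugitive emissions from fuels"
            else en.fugitive_emission(fuel(5.0, category=c), 0.05)
            for c in en.ENERGY_CATEGORIES
        ]
        table = InventoryTable.from_estimates(ests)
        per_cat = table.aggregate(["category"])
        assert len(per_cat) == 11
        assert per_cat["n2o_n_gg"].sum() == pytest.approx(
            table.aggregate([])["n2o_n_gg"].iloc[0], abs=1e-12
        )


def plant(production=500.0, abated=False, df=0.0, uf=0.0, product="adipic"):
    return ind.PlantRecord(
        year=2010, province="Henan", product=product,
        production_kt=production, abated=abated, df=df, uf=uf,
    )


class TestIndustry:
    def test_unabated_hand_arithmetic(self):
        # 500 kt x 0.3 t N2O/t -> 150 kt N2O (EF 300 kg/t)
        est = ind.production_emission(plant(), 300.0)
        assert est.n2o_gg == pytest.approx(150.0, rel=1e-12)

    def test_full_destruction_is_zero(self):
        est = ind.production_emission(plant(abated=True, df=1.0, uf=1.0), 300.0)
        assert est.n2o_n_gg == 0.0

    def test_partial_abatement(self):
        est = ind.production_emission(plant(abated=True, df=0.9, uf=0.95), 300.0)
        assert est.n2o_gg == pytest.approx(150.0 * (1 - 0.855), rel=1e-12)

    def test_df_out_of_range(self):
        with pytest.raises(ValueError):
            plant(abated=True, df=1.5)

    @settings(derandomize=True, max_examples=50)
    @given(df=st.floats(0.0, 1.0), uf=st.floats(0.0, 1.0))
    def test_abated_never_exceeds_unabated(self, df, uf):
        un = ind.production_emission(plant(), 300.0).n2o_n_gg
        ab = ind.production_emission(plant(abated=True, df=df, uf=uf), 300.0).n2o_n_gg
        assert ab <= un
        if df * uf == 0:
            assert ab == pytest.approx(un, rel=1e-12)
        elif df * uf > 1e-12:  # below that, 1 - df*uf rounds to 1.0
            assert ab < un

    def test_abatement_registry_window(self):
        reg = ind.AbatementRegistry()
        assert reg.abatement_for("Henan", 2010) is not None
        assert reg.abatement_for("Henan", 2015) is None
        assert reg.abatement_for("Shandong", 2010) is None
        cont = ind.AbatementRegistry(continue_after_window=True)
        assert cont.abatement_for("Henan", 2015) is not None

    def test_growing_production_gives_rising_trajectory(self):
        years = np.arange(2005, 2021)
        production = 100.0 * np.exp(0.15 * (years - 2005))
        reg = ind.AbatementRegistry()
        series = []
        for y, p in zip(years, production):
            ab = reg.abatement_for("Henan", int(y))
            rec = ind.PlantRecord(
                year=int(y), province="Henan", product="adipic",
                production_kt=float(p), abated=ab is not None,
                df=ab.df if ab else 0.0, uf=ab.uf if ab else 0.0,
            )
            series.append(ind.production_emission(rec, 300.0).n2o_n_gg)
        # strictly increasing outside the abatement window edges
        assert series[-1] > series[0]
        post_2012 = series[8:]
        assert all(b > a for a, b in zip(post_2012, post_2012[1:]))


def ww(pop=1e6, protein=30.0, sludge=0.0, **kw):
    return ws.WastewaterRecord(
        year=2010, province="Hunan", population=pop, protein_kg=protein,
        sludge_n_gg=sludge, **kw,
    )


class TestWaste:
    def test_protein_pathway_hand_arithmetic(self):
        # 1e6 people x 30 kg x 0.16 = 4.8 Gg N; x 0.005 = 0.024 Gg N2O-N
        est = ws.wastewater_emission(ww(), 0.005)
        assert est.n2o_n_gg == pytest.approx(0.024, rel=1e-12)
        assert est.n2o_gg == pytest.approx(0.0377, rel=1e-3)

    def test_zero_population(self):
        assert ws.wastewater_emission(ww(pop=0), 0.005).n2o_n_gg == 0.0

    def test_sludge_floor_clamps_to_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="n2obudget.waste"):
            est = ws.wastewater_emission(ww(sludge=100.0), 0.005)
        assert est.n2o_n_gg == 0.0
        assert any("clamping" in r.message for r in caplog.records)

    def test_monotone_in_population_protein_and_sludge(self):
        base = ws.wastewater_emission(ww(), 0.005).n2o_n_gg
        assert ws.wastewater_emission(ww(pop=2e6), 0.005).n2o_n_gg > base
        assert ws.wastewater_emission(ww(protein=40), 0.005).n2o_n_gg > base
        assert ws.wastewater_emission(ww(sludge=1.0), 0.005).n2o_n_gg < base

    def test_solid_waste_hand_arithmetic(self):
        rec = ws.SolidWasteRecord(
            year=2010, province="Hunan", compost_kt=100.0, incin_kt=0.0,
        )
        # 100 kt x 0.0006 t/t = 60 t N2O
        assert ws.solid_waste_emission(rec).n2o_gg == pytest.approx(0.06, rel=1e-12)

    def test_solid_waste_zero_and_linearity(self):
        zero = ws.SolidWasteRecord(year=2010, province="Hunan")
        assert ws.solid_waste_emission(zero).n2o_n_gg == 0.0
        one = ws.SolidWasteRecord(year=2010, province="Hunan",
                                  compost_kt=50.0, incin_kt=20.0)
        double = ws.SolidWasteRecord(year=2010, province="Hunan",
                                     compost_kt=100.0, incin_kt=40.0)
        assert ws.solid_waste_emission(double).n2o_n_gg == pytest.approx(
            2 * ws.solid_waste_emission(one).n2o_n_gg, rel=1e-12
        )
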