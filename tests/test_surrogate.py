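"""Stoichiometric surrogate: mass closure, plant chain, MESP economics."""
import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biorefuq.surrogate import (
    DEFAULT_COMPOSITION,
    CompositionProfile,
    EconConfig,
    MassClosureError,
    PlantState,
    Reaction,
    Stream,
    SurrogateError,
    apply_reactions,
    calibrate_economics,
    compute_mesp,
    enzymatic_hydrolysis_slates,
    fermentation_slate,
    pretreatment_slate,
    simulate_plant,
)

#: overrides silencing every sugar-producing / ethanol-producing reaction
ALL_ZERO = {
    "pt_glucan_to_glucose": 0.0, "pt_glucan_to_glucose_oligomer": 0.0,
    "pt_glucan_to_hmf": 0.0, "pt_glucan_to_degradation": 0.0,
    "xylan_to_xylose": 0.0, "pt_xylan_to_xylose_secondary": 0.0,
    "pt_xylan_to_xylose_oligomer": 0.0, "pt_xylan_to_furfural": 0.0,
    "pt_xylan_to_tar": 0.0, "arabinan_to_arabinose": 0.0,
    "pt_arabinan_to_arabinose_oligomer": 0.0, "pt_arabinan_to_furfural": 0.0,
    "pt_galactan_to_galactose": 0.0, "pt_galactan_to_galactose_oligomer": 0.0,
    "pt_galactan_to_hmf": 0.0, "pt_mannan_to_mannose": 0.0,
    "pt_mannan_to_mannose_oligomer": 0.0, "pt_mannan_to_hmf": 0.0,
    "pt_sucrose_to_glucose": 0.0, "pt_extractives_to_acetic_acid": 0.0,
    "pt_lignin_solubilization": 0.0,
    "cellulose_to_glucose": 0.0, "eh_cellulose_to_cellobiose": 0.0,
    "eh_cellulose_to_glucose_oligomer": 0.0, "eh_cellobiose_to_glucose": 0.0,
    "glucose_to_ethanol": 0.0, "xylose_to_ethanol": 0.0,
    "ferm_arabinose_to_ethanol": 0.0, "ferm_galactose_to_ethanol": 0.0,
    "ferm_mannose_to_ethanol": 0.0,
}


class TestReaction:
    def test_water_term_derived_from_conservation(self):
        r = Reaction("x", "xylan", "xylose", 150 / 132, 0.9)
        assert r.water_term == pytest.approx(18 / 132, abs=1e-12)

    def test_inconsistent_water_term_rejected(self):
        with pytest.raises(SurrogateError, match="conserved"):
            Reaction("x", "xylan", "xylose", 150 / 132, 0.9, water_term=0.5)

    def test_coproducts_count_toward_conservation(self):
        r = Reaction("f", "glucose", "ethanol", 0.511, 0.95,
                     coproducts=(("co2", 0.489),))
        assert r.water_term == pytest.approx(0.0, abs=1e-12)


class TestApplyReactions:
    def test_zero_yields_leave_stream_unchanged(self):
        s = Stream({"xylan": 100.0, "water": 50.0})
        slate = [Reaction("x", "xylan", "xylose", 150 / 132, 0.0)]
        assert apply_reactions(s, slate) == s

    def test_anhydro_hydrolysis_arithmetic(self):
        s = Stream({"xylan": 100.0, "water": 50.0})
        slate = [Reaction("x", "xylan", "xylose", 150 / 132, 0.90)]
        out = apply_reactions(s, slate)
        assert out["xylose"] == pytest.approx(90 * 150 / 132)   # 102.27
        assert out["xylan"] == pytest.approx(10.0)
        assert out["water"] == pytest.approx(50.0 - 90 * 18 / 132)  # -12.27

    def test_competing_yields_over_unity_name_the_reactant(self):
        s = Stream({"glucose": 10.0, "water": 10.0})
        slate = [Reaction("a", "glucose", "ethanol", 0.511, 0.6,
                          coproducts=(("co2", 0.489),)),
                 Reaction("b", "glucose", "lactic_acid", 1.0, 0.5)]
        with pytest.raises(MassClosureError, match="glucose"):
            apply_reactions(s, slate)

    @settings(deadline=None, max_examples=30)
    @given(
        xylan=st.floats(0.0, 500.0),
        glucan=st.floats(0.0, 500.0),
        y1=st.floats(0.0, 1.0),
        y2=st.floats(0.0, 1.0),
    )
    def test_total_mass_conserved(self, xylan, glucan, y1, y2):
        s = Stream({"xylan": xylan, "glucan": glucan, "water": 1000.0})
        slate = [
            Reaction("a", "xylan", "xylose", 150 / 132, y1),
            Reaction("b", "glucan", "hmf", 126 / 162, y2),
        ]
        out = apply_reactions(s, slate)
        assert out.total == pytest.approx(s.total, rel=1e-12)

    def test_default_slates_conserve_plant_mass(self):
        plant = simulate_plant()
        feed_total = plant.feed_rate * (1 + 2.5)  # dry feed + process water
        assert plant.outlet.total == pytest.approx(feed_total, rel=1e-9)


class TestCompositionProfile:
    def test_default_closes_to_one(self):
        assert DEFAULT_COMPOSITION.total == pytest.approx(1.0, abs=1e-9)

    def test_updates_absorb_closure_into_extractives(self):
        c = DEFAULT_COMPOSITION.with_updates(glucan=0.40)
        assert c.total == pytest.approx(1.0, abs=1e-9)
        assert c.extractives < DEFAULT_COMPOSITION.extractives

    def test_update_without_headroom_rejected(self):
        with pytest.raises(SurrogateError):
            DEFAULT_COMPOSITION.with_updates(glucan=0.95)

    def test_malformed_total_rejected(self):
        with pytest.raises(SurrogateError):
            CompositionProfile(glucan=0.5, extractives=0.164)


class TestSimulatePlant:
    def test_slate_sizes_match_the_canonical_reaction_counts(self):
        s1, s2 = enzymatic_hydrolysis_slates()
        assert len(pretreatment_slate()) == 21
        assert len(s1) + len(s2) == 8
        assert len(fermentation_slate()) == 31

    def test_all_zero_yields_make_no_ethanol(self):
        plant = simulate_plant(yields=ALL_ZERO)
        assert plant.ethanol == 0.0

    def test_stoichiometric_maximum_from_glucan_and_xylan(self):
        comp = DEFAULT_COMPOSITION
        overrides = dict(ALL_ZERO, **{
            "cellulose_to_glucose": 1.0, "xylan_to_xylose": 1.0,
            "glucose_to_ethanol": 1.0, "xylose_to_ethanol": 1.0,
        })
        plant = simulate_plant(comp, overrides, feed_rate=1.0)
        expected = 0.511 * (comp.glucan * 180 / 162 + comp.xylan * 150 / 132)
        assert plant.ethanol == pytest.approx(expected, rel=1e-9)

    def test_glucose_derived_ethanol_linear_in_hydrolysis_yield(self):
        overrides = dict(ALL_ZERO, **{"glucose_to_ethanol": 0.95})
        e = {}
        for y in (0.8, 0.4):
            plant = simulate_plant(
                yields=dict(overrides, **{"cellulose_to_glucose": y}),
                feed_rate=1.0)
            e[y] = plant.ethanol
        assert e[0.4] == pytest.approx(e[0.8] / 2, rel=1e-12)

    def test_unknown_override_rejected(self):
        with pytest.raises(SurrogateError, match="unknown"):
            simulate_plant(yields={"nope": 0.5})


class TestEconomics:
    def test_mesp_is_net_cost_over_gallons(self):
        plant = PlantState(feed_rate=1.0, ethanol=50e6 * 2.988 / 8410.0,
                           boiler_fuel=0.0, outlet=Stream(), byproducts={})
        econ = EconConfig(annualized_capital=100e6, fixed_operating=0.0,
                          feedstock_price=0.0, variable_cost_per_kg_feed=0.0,
                          power_price=0.0)
        res = compute_mesp(plant, econ)
        assert res.mesp == pytest.approx(2.00, rel=1e-9)
        assert res.annual_ethanol_gal == pytest.approx(50e6, rel=1e-9)

    def test_zero_net_cost_zero_mesp(self):
        plant = PlantState(feed_rate=1.0, ethanol=100.0, boiler_fuel=0.0,
                           outlet=Stream(), byproducts={})
        econ = EconConfig(annualized_capital=0.0, fixed_operating=0.0,
                          feedstock_price=0.0, variable_cost_per_kg_feed=0.0,
                          power_price=0.0)
        assert compute_mesp(plant, econ).mesp == 0.0

    def test_zero_ethanol_is_an_error(self):
        plant = PlantState(feed_rate=1.0, ethanol=0.0, boiler_fuel=0.0,
                           outlet=Stream(), byproducts={})
        with pytest.raises(SurrogateError, match="MESP"):
            compute_mesp(plant, EconConfig())

    def test_operating_hours_bounded_by_the_calendar(self):
        with pytest.raises(SurrogateError):
            EconConfig(operating_hours=9000)

    def test_calibration_hits_target_exactly_and_is_idempotent(self):
        econ = calibrate_economics(target_mesp=1.0)
        mesp1 = compute_mesp(simulate_plant(), econ).mesp
        assert mesp1 == pytest.approx(1.0, abs=1e-9)
        econ2 = calibrate_economics(target_mesp=2.0, econ=econ)
        mesp2 = compute_mesp(simulate_plant(), econ2).mesp
        assert mesp2 == pytest.approx(2.0, abs=1e-9)

    def test_raising_conversions_lowers_mesp(self, calibrated_econ):
        base = compute_mesp(simulate_plant(), calibrated_econ).mesp
        better = {
            "xylan_to_xylose": 0.95, "arabinan_to_arabinose": 0.95,
            "cellulose_to_glucose": 0.95, "glucose_to_ethanol": 1.0,
            "xylose_to_ethanol": 0.95,
        }
        improved = compute_mesp(simulate_plant(yields=better),
                                calibrated_econ).mesp
        assert improved < base

    @pytest.mark.parametrize("name,hi", [
        ("xylan_to_xylose", 0.93), ("cellulose_to_glucose", 0.93),
        ("glucose_to_ethanol", 0.98), ("xylose_to_ethanol", 0.90),
        ("arabinan_to_arabinose", 0.93),
    ])
    def test_mesp_strictly_decreasing_in_each_key_yield(
            self, calibrated_econ, name, hi):
        lo_m = compute_mesp(simulate_plant(yields={name: 0.80}),
                            calibrated_econ).mesp
        hi_m = compute_mesp(simulate_plant(yields={name: hi}),
                            calibrated_econ).mesp
        assert hi_m < lo_m

    @pytest.mark.parametrize("component", ["glucan", "xylan"])
    def test_mesp_strictly_decreasing_in_carbohydrate_content(
            self, calibrated_econ, component):
        lo_c = DEFAULT_COMPOSITION.with_updates(**{
            component: getattr(DEFAULT_COMPOSITION, component) * 0.9})
        hi_c = DEFAULT_COMPOSITION.with_updates(**{
            component: getattr(DEFAULT_COMPOSITION, component) * 1.1})
        lo_m = compute_mesp(simulate_plant(lo_c), calibrated_econ).mesp
        hi_m = compute_mesp(simulate_plant(hi_c), calibrated_econ).mesp
        assert hi_m < lo_m
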