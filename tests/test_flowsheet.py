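"""Unit-operation models and full-flowsheet mass-balance solving."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsfplant import Flowsheet, Stream, UnitSpec, build_default_flowsheet, simulate
from bsfplant.flowsheet import (
    COMPONENTS,
    AmbiguousCutError,
    ConfigurationError,
    FlowsheetError,
    PhaseError,
    TopologyError,
    adsorb_water,
    centrifuge,
    condense,
    distill_sharp,
    freeze_dry,
    grind,
    hydrolyze,
    membrane_filter,
    wash,
)


def stream(masses, phase="solid-slurry", **kw):
    return Stream(label="test", masses=masses, phase=phase, **kw)


class TestWash:
    def test_removal_fractions(self):
        """66% of ash and 38% of cellulose report to the wash waste."""
        feed = stream({"ash": 100.0, "cellulose": 200.0, "water": 500.0})
        washed, waste = wash(feed, wash_water=1000.0, ash_removal=0.66, cellulose_removal=0.38)
        assert waste.mass("ash") == pytest.approx(66.0)
        assert washed.mass("ash") == pytest.approx(34.0)
        assert waste.mass("cellulose") == pytest.approx(76.0)
        assert waste.mass("water") == 1000.0
        assert washed.mass("water") == 500.0  # wash water does not dilute the larvae

    def test_identity_when_no_removal(self):
        feed = stream({"ash": 10.0, "protein": 20.0})
        washed, waste = wash(feed, 0.0, 0.0, 0.0)
        assert washed.masses == feed.masses
        assert waste.total == 0.0

    def test_invalid_removal_rejected(self):
        with pytest.raises(ConfigurationError):
            wash(stream({"ash": 1.0}), 0.0, 1.2, 0.0)


class TestGrind:
    def test_duration_from_throughput(self):
        feed = stream({"water": 9174.0})
        out, duration = grind(feed, 9174.0)
        assert duration == pytest.approx(1.0)
        assert out.masses == feed.masses

    def test_empty_feed_zero_duration(self):
        _, duration = grind(stream({}), 9174.0)
        assert duration == 0.0

    def test_nonpositive_throughput_rejected(self):
        with pytest.raises(ConfigurationError):
            grind(stream({"water": 1.0}), 0.0)


class TestHydrolyze:
    def test_enzyme_mass_added(self):
        feed = stream({"water": 9000.0, "protein": 1000.0})
        slurry = hydrolyze(feed, enzyme=100.0, conversion=0.5)
        assert slurry.total == pytest.approx(10_100.0)
        assert slurry.temperature == 60.0

    def test_zero_conversion_keeps_protein(self):
        feed = stream({"protein": 500.0})
        slurry = hydrolyze(feed, 10.0, 0.0)
        assert slurry.mass("protein") == 500.0
        assert slurry.mass("hydrolyzed_protein") == 0.0

    def test_full_conversion_bookkeeping(self):
        feed = stream({"protein": 2894.0, "water": 100.0})
        slurry = hydrolyze(feed, 0.0, 1.0)
        assert slurry.mass("hydrolyzed_protein") == pytest.approx(2894.0)
        assert slurry.mass("protein") == 0.0


class TestMembraneFilter:
    def test_rejection_split(self):
        feed = stream({"cellulose": 1000.0, "water": 10_000.0})
        permeate, retentate, _, _ = membrane_filter(
            feed, "cellulose", rejection=0.999, denaturation=0.0, flux=20.0, max_density=1100.0
        )
        assert retentate.mass("cellulose") == pytest.approx(999.0)
        assert permeate.mass("cellulose") == pytest.approx(1.0)
        assert permeate.total + retentate.total == pytest.approx(feed.total)

    def test_zero_rejection_passes_everything(self):
        feed = stream({"cellulose": 100.0, "water": 1000.0})
        permeate, retentate, _, _ = membrane_filter(feed, "cellulose", 0.0, 0.0, 20.0, 1100.0)
        assert retentate.total == 0.0
        assert permeate.masses == feed.masses

    def test_area_from_flux(self):
        """20 m3/h of feed at 20 L/m2 h needs 1000 m2 of membrane."""
        feed = stream({"water": 20_000.0})  # 20 m3 at 1000 kg/m3
        _, _, area, _ = membrane_filter(feed, "cellulose", 0.0, 0.0, 20.0, 1100.0, duration=1.0)
        assert area == pytest.approx(1000.0)

    def test_denaturation_relabels_crossing_protein(self):
        feed = stream({"protein": 100.0, "water": 1000.0})
        permeate, _, _, _ = membrane_filter(feed, "cellulose", 0.0, 0.05, 20.0, 1100.0)
        assert permeate.mass("denatured_protein") == pytest.approx(5.0)
        assert permeate.mass("protein") == pytest.approx(95.0)
        assert permeate.total == pytest.approx(feed.total)

    def test_retained_water_respects_max_density(self):
        feed = stream({"cellulose": 1100.0, "water": 10_000.0})
        _, retentate, _, warns = membrane_filter(feed, "cellulose", 1.0, 0.0, 20.0, 1100.0)
        vol_l = retentate.mass("water") + retentate.mass("cellulose") / 1.5
        assert retentate.mass("cellulose") / vol_l <= 1.1 * (1 + 1e-9)
        assert warns == []

    def test_overridden_retained_water_warns_on_density(self):
        feed = stream({"cellulose": 1100.0, "water": 10_000.0})
        _, _, _, warns = membrane_filter(
            feed, "cellulose", 1.0, 0.0, 20.0, 1100.0, retained_water=1.0
        )
        assert any("max density" in w for w in warns)

    def test_unknown_component_rejected(self):
        with pytest.raises(ConfigurationError):
            membrane_filter(stream({"water": 1.0}), "unobtainium", 0.5, 0.0, 20.0, 1100.0)


class TestCentrifuge:
    PHASE_MAP = {
        "lauric_acid": "light", "protein": "heavy", "cellulose": "aqueous", "ash": "aqueous",
    }

    def test_ideal_split(self):
        feed = stream({"lauric_acid": 3000.0, "protein": 2000.0, "water": 5000.0})
        oil, meal, aqueous = centrifuge(feed, self.PHASE_MAP)
        assert oil.mass("lauric_acid") == 3000.0
        assert meal.mass("protein") == 2000.0
        assert aqueous.mass("water") == 5000.0
        assert oil.total + meal.total + aqueous.total == pytest.approx(feed.total)

    def test_fat_carryover_leaks_to_protein(self):
        feed = stream({"lauric_acid": 1000.0, "water": 100.0})
        oil, meal, _ = centrifuge(feed, self.PHASE_MAP, carryover=0.02)
        assert meal.mass("lauric_acid") == pytest.approx(20.0)
        assert oil.mass("lauric_acid") == pytest.approx(980.0)

    def test_water_split_fractions(self):
        feed = stream({"water": 1000.0})
        oil, meal, aqueous = centrifuge(feed, {}, water_to_light=0.01, water_to_heavy=0.30)
        assert oil.mass("water") == pytest.approx(10.0)
        assert meal.mass("water") == pytest.approx(300.0)
        assert aqueous.mass("water") == pytest.approx(690.0)

    def test_unmapped_component_rejected(self):
        with pytest.raises(ConfigurationError):
            centrifuge(stream({"mystery": 1.0}), self.PHASE_MAP)


class TestDistillSharp:
    def test_sharp_split_by_boiling_point(self):
        """Everything boiling below the cut goes overhead; the rest to bottoms."""
        feed = stream({"water": 10.0, "lauric_acid": 20.0, "myristic_acid": 30.0,
                       "palmitic_acid": 15.0, "stearic_acid": 25.0}, phase="liquid")
        dist, bot, _, _, warns = distill_sharp(feed, 310.0, 14.404, 22)
        assert dist.masses == {"water": 10.0, "lauric_acid": 20.0}
        assert bot.masses == {"myristic_acid": 30.0, "palmitic_acid": 15.0, "stearic_acid": 25.0}
        assert dist.phase == "vapor" and bot.phase == "liquid"
        assert warns == []

    def test_degenerate_cut_warns(self):
        feed = stream({"stearic_acid": 100.0}, phase="liquid")
        dist, bot, _, _, warns = distill_sharp(feed, 310.0, 1.0, 10)
        assert dist.total == 0.0
        assert bot.masses == feed.masses
        assert any("degenerate" in w for w in warns)

    def test_zero_reflux_duty(self):
        feed = stream({"lauric_acid": 100.0, "stearic_acid": 50.0}, phase="liquid")
        _, _, qc, qr, _ = distill_sharp(feed, 310.0, 0.0, 10)
        assert qc == pytest.approx(100.0 * COMPONENTS["lauric_acid"].latent_heat)
        assert qr == qc

    def test_cut_on_boiling_point_ambiguous(self):
        feed = stream({"lauric_acid": 1.0, "stearic_acid": 1.0}, phase="liquid")
        with pytest.raises(AmbiguousCutError):
            distill_sharp(feed, 298.8, 1.0, 10)

    @settings(deadline=None, max_examples=50)
    @given(
        masses=st.dictionaries(
            st.sampled_from(["water", "lauric_acid", "myristic_acid",
                             "palmitic_acid", "stearic_acid"]),
            st.floats(0.1, 1e5), min_size=1,
        ),
        cut=st.sampled_from([150.0, 310.0, 335.0, 352.0]),
    )
    def test_ordering_property(self, masses, cut):
        """No component below the cut in bottoms; none above it in distillate."""
        dist, bot, _, _, _ = distill_sharp(stream(masses, phase="liquid"), cut, 1.0, 10)
        for comp in dist.masses:
            assert COMPONENTS[comp].boiling_point < cut
        for comp in bot.masses:
            assert COMPONENTS[comp].boiling_point > cut
        assert dist.total + bot.total == pytest.approx(sum(masses.values()))


class TestCondense:
    def test_requires_vapor(self):
        with pytest.raises(PhaseError):
            condense(stream({"water": 1.0}, phase="liquid"), 80.0)

    def test_zero_mass_zero_duty(self):
        liq, duty = condense(stream({}, phase="vapor"), 80.0)
        assert duty == 0.0 and liq.total == 0.0

    def test_composition_preserved(self):
        vap = stream({"lauric_acid": 10.0, "water": 2.0}, phase="vapor")
        liq, _ = condense(vap, 80.0)
        assert liq.masses == vap.masses
        assert liq.phase == "liquid" and liq.temperature == 80.0

    def test_duty_formula(self):
        c = COMPONENTS["lauric_acid"]
        _, duty = condense(stream({"lauric_acid": 1000.0}, phase="vapor"), 80.0)
        assert duty == pytest.approx(1000.0 * c.latent_heat + 1000.0 * c.heat_capacity * (298.8 - 80.0))


class TestAdsorbWater:
    def test_complete_water_removal(self):
        feed = stream({"lauric_acid": 500.0, "water": 50.0}, phase="liquid")
        dry, reusable = adsorb_water(feed, backwash_water=100.0)
        assert dry.masses == {"lauric_acid": 500.0}
        assert reusable.mass("water") == pytest.approx(150.0)
        assert dry.total + reusable.total == pytest.approx(feed.total + 100.0)

    def test_water_free_feed_identity(self):
        feed = stream({"lauric_acid": 500.0}, phase="liquid")
        dry, reusable = adsorb_water(feed)
        assert dry.masses == feed.masses
        assert reusable.total == 0.0

    def test_requires_liquid(self):
        with pytest.raises(PhaseError):
            adsorb_water(stream({"water": 1.0}, phase="vapor"))


class TestFreezeDry:
    def test_complete_drying(self):
        feed = stream({"protein": 900.0, "water": 1100.0})
        meal, exhaust, _, warns = freeze_dry(feed, final_moisture=0.0)
        assert meal.masses == {"protein": 900.0}
        assert exhaust.mass("water") == pytest.approx(1100.0)
        assert warns == []

    def test_layer_model_duration(self):
        _, _, duration, _ = freeze_dry(stream({"protein": 1.0, "water": 1.0}), 0.0,
                                       sublimation_rate=10.0, tray_depth=10.0)
        assert duration == pytest.approx(1.0)

    def test_target_moisture_solved(self):
        feed = stream({"protein": 950.0, "water": 950.0})
        meal, _, _, _ = freeze_dry(feed, 0.05)
        assert meal.mass("water") == pytest.approx(50.0)
        assert meal.mass("water") / meal.total == pytest.approx(0.05)

    def test_already_dry_is_noop_with_warning(self):
        feed = stream({"protein": 950.0, "water": 10.0})
        meal, exhaust, _, warns = freeze_dry(feed, 0.05)
        assert meal.masses == feed.masses
        assert exhaust.total == 0.0
        assert warns


class TestSimulate:
    def test_default_plant_closure(self, default_plant, control_feed):
        sim = simulate(default_plant, control_feed)
        assert sim.closure_residual < 1e-9

    def test_empty_feed_all_empty(self, default_plant):
        sim = simulate(default_plant, Stream("Larvae feed", {}))
        assert all(s.total == 0.0 for s in sim.streams.values())

    def test_lauric_product_analytic(self, default_plant, control, default_profile):
        """With zero configured losses, lauric product = feed fat x lauric fraction."""
        from bsfplant import larvae_feed_stream, wet_basis_fractions
        cf = wet_basis_fractions(control)
        feed = larvae_feed_stream(10_000.0, cf, default_profile)
        sim = simulate(default_plant, feed)
        expected = 10_000.0 * cf.crude_fat * default_profile.lauric
        assert sim.streams["Lauric acid product"].total == pytest.approx(expected, rel=1e-9)

    def test_stream_content_contract(self, default_plant, control_feed):
        """Simulated stream compositions match the expected flow-content table."""
        sim = simulate(default_plant, control_feed)
        expected_subsets = {
            "Wastes 1": {"ash", "cellulose", "water"},
            "Cellulose waste": {"cellulose", "water"},
            "Ash waste": {"ash", "water"},
            "Wastes 2": {"cellulose", "water"},
            "Reusable water 2": {"water"},
            "Lauric acid product": {"lauric_acid"},
            "Myristic acid product": {"myristic_acid"},
            "Palmitic acid product": {"palmitic_acid"},
            "Stearic acid product": {"stearic_acid"},
            "S-110": {"lauric_acid", "water"},
            "Drying exhaust": {"water"},
        }
        for label, allowed in expected_subsets.items():
            assert set(sim.streams[label].masses) <= allowed, label

    @settings(deadline=None, max_examples=50)
    @given(
        water=st.floats(100.0, 1e5), ash=st.floats(0.0, 1e4),
        protein=st.floats(0.0, 1e4), cellulose=st.floats(0.0, 1e4),
        fat=st.floats(0.0, 1e4),
    )
    def test_closure_on_random_feeds(self, water, ash, protein, cellulose, fat):
        feed_masses = {"water": water, "ash": ash, "protein": protein,
                       "cellulose": cellulose,
                       "lauric_acid": 0.5 * fat, "myristic_acid": 0.2 * fat,
                       "palmitic_acid": 0.2 * fat, "stearic_acid": 0.1 * fat}
        fs = build_default_flowsheet()
        sim = simulate(fs, Stream("Larvae feed", feed_masses, phase="solid-slurry"))
        assert sim.closure_residual < 1e-9

    def test_toy_flowsheet_matches_hand_composition(self):
        """3-unit chain equals hand-composed split matrices exactly."""
        units = [
            UnitSpec("W", "washer", ("feed",), ("washed", "w1"),
                     {"wash_water": 0.0, "ash_removal": 0.5, "cellulose_removal": 0.25}),
            UnitSpec("F", "membrane_filter", ("washed",), ("perm", "ret"),
                     {"rejected_component": "cellulose", "rejection": 0.8,
                      "denaturation": 0.0, "flux": 20.0, "max_density": 1100.0,
                      "retained_water": 0.0}),
            UnitSpec("C", "centrifuge", ("perm",), ("oil", "meal", "aq"),
                     {"phase_map": {"lauric_acid": "light", "ash": "aqueous",
                                    "cellulose": "aqueous"}}),
        ]
        fs = Flowsheet(units=units)
        feed = Stream("feed", {"ash": 100.0, "cellulose": 80.0, "lauric_acid": 60.0,
                               "water": 200.0}, phase="solid-slurry")
        sim = simulate(fs, feed)
        # hand-composed: wash halves ash, quarters cellulose; filter keeps 80% of
        # remaining cellulose in the retentate; centrifuge routes the rest.
        assert sim.streams["w1"].masses == pytest.approx({"ash": 50.0, "cellulose": 20.0})
        assert sim.streams["ret"].masses == pytest.approx({"cellulose": 0.8 * 60.0})
        assert sim.streams["oil"].masses == pytest.approx({"lauric_acid": 60.0})
        assert sim.streams["aq"].mass("cellulose") == pytest.approx(0.2 * 60.0)
        assert sim.streams["aq"].mass("ash") == pytest.approx(50.0)
        assert sim.streams["aq"].mass("water") == pytest.approx(200.0)

    def test_cycle_detection(self):
        units = [
            UnitSpec("A", "grinder", ("x",), ("y",), {"throughput": 1.0}),
            UnitSpec("B", "grinder", ("y",), ("x",), {"throughput": 1.0}),
        ]
        with pytest.raises(TopologyError):
            Flowsheet(units=units)

    def test_missing_parameters_rejected_at_build(self):
        with pytest.raises(ConfigurationError):
            UnitSpec("W", "washer", ("a",), ("b", "c"), {"wash_water": 1.0})

    def test_unit_error_tagged_with_unit_id(self, default_plant):
        bad = build_default_flowsheet(conversion=1.5)
        feed = Stream("Larvae feed", {"water": 1.0, "protein": 1.0}, phase="solid-slurry")
        with pytest.raises(FlowsheetError, match="BR-101"):
            simulate(bad, feed)
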