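"""Quadrat and core arithmetic against hand-computed oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spawnfeast.survey import (
    EggGeometry,
    QuadratObservation,
    SedimentCore,
    StratumLayout,
    amphipod_core_density,
    attached_egg_count,
    loose_egg_count,
    quadrat_egg_mass,
    strip_amphipod_mass,
    strip_egg_mass,
)

GEOM = EggGeometry()
FOOTPRINT = math.pi * (0.74e-3) ** 2  # independent hand computation


def quad(**kw):
    base = dict(beach_id="B1", survey_date="2012-04-05", stratum="mid_2_3m")
    base.update(kw)
    return QuadratObservation(**base)


class TestLooseEggCount:
    def test_zero_cover_is_zero_eggs(self):
        assert loose_egg_count(quad(loose_cover_pct=0.0)) == 0.0

    def test_half_cover_two_layers(self):
        # 50% of 0.25 m2 = 0.125 m2; / one-egg footprint; x mean layers 2
        obs = quad(loose_cover_pct=50.0, loose_layer_counts=(2, 2, 2, 2, 2))
        expected = 0.125 / FOOTPRINT * 2
        assert loose_egg_count(obs) == pytest.approx(expected)
        assert expected == pytest.approx(145320, abs=1.0)

    def test_footprint_identity_single_egg(self):
        # full cover, one layer, quadrat the size of one egg -> exactly 1 egg
        obs = quad(
            loose_cover_pct=100.0, loose_layer_counts=(1,), quadrat_area_m2=GEOM.footprint_m2
        )
        assert loose_egg_count(obs) == pytest.approx(1.0)

    def test_positive_cover_without_layers_raises_naming_quadrat(self):
        obs = quad(loose_cover_pct=10.0)
        with pytest.raises(ValueError, match="B1"):
            loose_egg_count(obs)

    def test_packing_fraction_scales_counts(self):
        obs = quad(loose_cover_pct=50.0, loose_layer_counts=(2,))
        dense = EggGeometry(packing_fraction=0.9069)
        assert loose_egg_count(obs, dense) == pytest.approx(
            0.9069 * loose_egg_count(obs, GEOM)
        )


class TestAttachedEggCount:
    def test_zero_cover(self):
        assert attached_egg_count(quad(attached_cover_pct=0.0)) == 0.0

    def test_forty_percent_three_by_two_layers(self):
        obs = quad(
            attached_cover_pct=40.0,
            attached_egg_layer_counts=(3, 3, 3),
            macrophyte_layer_counts=(2, 2),
        )
        expected = 0.1 / FOOTPRINT * 3 * 2
        assert attached_egg_count(obs) == pytest.approx(expected)
        assert expected == pytest.approx(348769, abs=1.0)

    def test_single_macrophyte_layer_reduces_to_loose_formula(self):
        attached = quad(
            attached_cover_pct=35.0,
            attached_egg_layer_counts=(2, 4),
            macrophyte_layer_counts=(1, 1, 1),
        )
        loose = quad(loose_cover_pct=35.0, loose_layer_counts=(2, 4))
        assert attached_egg_count(attached) == pytest.approx(loose_egg_count(loose))


class TestQuadratEggMass:
    def test_mass_of_half_cover_quadrat(self):
        obs = quad(loose_cover_pct=50.0, loose_layer_counts=(2, 2, 2, 2, 2))
        expected_kg = (0.125 / FOOTPRINT * 2) * 0.27e-6
        assert quadrat_egg_mass(obs) == pytest.approx(expected_kg)
        assert expected_kg == pytest.approx(0.0392, abs=5e-4)

    def test_empty_quadrat_and_single_egg(self):
        assert quadrat_egg_mass(quad()) == 0.0
        one_egg = quad(
            loose_cover_pct=100.0, loose_layer_counts=(1,), quadrat_area_m2=GEOM.footprint_m2
        )
        assert quadrat_egg_mass(one_egg) == pytest.approx(2.7e-7)  # 0.27 mg in kg


class TestStripEggMass:
    def test_all_empty_quadrats(self):
        layout = StratumLayout("B1", {"mid_2_3m": 5.0})
        assert strip_egg_mass([quad(), quad()], layout) == 0.0

    def test_uniform_density_times_width(self):
        # one stratum, width 10 m, uniform 0.01 kg/m2
        target_per_quadrat = 0.01 * 0.25  # kg in a 0.25 m2 quadrat
        layers = 2
        cover = target_per_quadrat / (layers * 0.27e-6) * FOOTPRINT / 0.25 * 100
        obs = quad(loose_cover_pct=cover, loose_layer_counts=(layers,) * 5)
        layout = StratumLayout("B1", {"mid_2_3m": 10.0})
        assert strip_egg_mass([obs], layout) == pytest.approx(0.1)

    def test_two_strata_sum_hand_computed(self):
        low = quad(stratum="low_1_2m", loose_cover_pct=20.0, loose_layer_counts=(1,))
        high = quad(stratum="high_3_4m", loose_cover_pct=60.0, loose_layer_counts=(3,))
        layout = StratumLayout("B1", {"low_1_2m": 4.0, "high_3_4m": 2.0})
        d_low = 0.2 * 0.25 / FOOTPRINT * 1 * 0.27e-6 / 0.25
        d_high = 0.6 * 0.25 / FOOTPRINT * 3 * 0.27e-6 / 0.25
        assert strip_egg_mass([low, high], layout) == pytest.approx(d_low * 4 + d_high * 2)

    def test_order_and_batch_split_invariance(self):
        a = quad(loose_cover_pct=30.0, loose_layer_counts=(2,))
        b = quad(loose_cover_pct=50.0, loose_layer_counts=(2,))
        layout = StratumLayout("B1", {"mid_2_3m": 6.0})
        assert strip_egg_mass([a, b], layout) == pytest.approx(strip_egg_mass([b, a], layout))
        # mean-preserving duplication leaves the stratum mean unchanged
        assert strip_egg_mass([a, b, a, b], layout) == pytest.approx(
            strip_egg_mass([a, b], layout)
        )

    def test_stratum_without_width_raises(self):
        obs = quad(loose_cover_pct=10.0, loose_layer_counts=(1,))
        with pytest.raises(ValueError, match="mid_2_3m"):
            strip_egg_mass([obs], StratumLayout("B1", {"low_1_2m": 3.0}))

    @given(
        scale=st.floats(min_value=0.01, max_value=1.0),
        width=st.floats(min_value=0.1, max_value=20.0),
    )
    @settings(deadline=None, max_examples=30)
    def test_homogeneity_in_cover_and_width(self, scale, width):
        base = quad(loose_cover_pct=80.0, loose_layer_counts=(2, 3))
        scaled = quad(loose_cover_pct=80.0 * scale, loose_layer_counts=(2, 3))
        layout1 = StratumLayout("B1", {"mid_2_3m": width})
        layout2 = StratumLayout("B1", {"mid_2_3m": 2 * width})
        m = strip_egg_mass([base], layout1)
        assert strip_egg_mass([scaled], layout1) == pytest.approx(scale * m)
        assert strip_egg_mass([base], layout2) == pytest.approx(2 * m)


class TestAmphipods:
    def test_zero_sorted_mass(self):
        core = SedimentCore("B1", "high_3_4m", sorted_dry_mass_g=0.0)
        assert amphipod_core_density(core) == 0.0

    def test_hand_computed_density(self):
        # 0.3 g sorted at 30% -> 1.0 g over pi*(0.053 m)^2 = 0.0088247 m2
        core = SedimentCore("B1", "high_3_4m", sorted_dry_mass_g=0.3)
        area = math.pi * 0.053**2
        assert amphipod_core_density(core) == pytest.approx(1.0 / area)
        assert amphipod_core_density(core) == pytest.approx(113.3, abs=0.1)

    def test_full_fraction_is_mass_over_area(self):
        core = SedimentCore("B1", "old_wrack", sorted_dry_mass_g=2.0, sorted_fraction=1.0)
        assert amphipod_core_density(core) == pytest.approx(2.0 / core.area_m2)

    def test_invalid_sorted_fraction_rejected(self):
        with pytest.raises(ValueError):
            SedimentCore("B1", "high_3_4m", sorted_dry_mass_g=1.0, sorted_fraction=0.0)

    def test_strip_mass_single_stratum(self):
        # density 25 g/m2 over width 4 m -> 100 g = 0.1 kg
        area = SedimentCore("B1", "high_3_4m", sorted_dry_mass_g=0).area_m2
        core = SedimentCore(
            "B1", "high_3_4m", sorted_dry_mass_g=25 * area * 0.30, sorted_fraction=0.30
        )
        layout = StratumLayout("B1", {"high_3_4m": 4.0})
        assert strip_amphipod_mass([core], layout) == pytest.approx(0.1)

    def test_strip_mass_mixed_strata_hand_summed(self):
        area = SedimentCore("B1", "high_3_4m", sorted_dry_mass_g=0).area_m2
        cores = [
            SedimentCore("B1", "high_3_4m", sorted_dry_mass_g=10 * area * 0.3),
            SedimentCore("B1", "fresh_wrack", sorted_dry_mass_g=40 * area * 0.3),
        ]
        layout = StratumLayout("B1", {"high_3_4m": 2.0, "fresh_wrack": 1.0})
        assert strip_amphipod_mass(cores, layout) == pytest.approx((10 * 2 + 40 * 1) / 1000)
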