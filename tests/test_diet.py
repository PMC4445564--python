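"""Scat-diet statistics: FO, FV, correction factors, and table rendering."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spawnfeast.diet import (
    ScatRecord,
    egg_edc_by_site_date,
    estimated_dietary_content,
    estimated_dietary_energy,
    faecal_volume,
    faecal_volume_table,
    format_display,
    frequency_of_occurrence,
    per_scat_edc,
    render_summary,
    scat_item_volume,
)


def scat(subsamples, scat_id="s1", beach="B1", date="2012-04-20"):
    return ScatRecord(scat_id, beach, date, tuple(subsamples))


class TestScatItemVolume:
    def test_item_in_all_subsamples(self):
        s = scat([{"graminoids": 3.0}] * 5)
        assert scat_item_volume(s)["graminoids"] == pytest.approx(3.0)

    def test_item_in_one_of_five_subsamples(self):
        s = scat([{"herring_eggs": 5.0}, {}, {}, {}, {}])
        assert scat_item_volume(s)["herring_eggs"] == pytest.approx(1.0)

    def test_empty_scat_empty_map(self):
        assert scat_item_volume(scat([{}] * 5)) == {}

    def test_overfull_subsample_rejected(self):
        with pytest.raises(ValueError, match="volumes sum"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scat([{"graminoids": 4.0, "seagrasses": 3.0}])

    def test_fewer_than_five_subsamples_warns(self):
        with pytest.warns(UserWarning, match="3 of 5"):
            scat([{"graminoids": 1.0}] * 3)


class TestFrequencyOfOccurrence:
    def test_three_of_five(self):
        scats = [scat([{"amphipods": 1.0}] * 5, scat_id=f"s{i}") for i in range(3)]
        scats += [scat([{"graminoids": 1.0}] * 5, scat_id=f"t{i}") for i in range(2)]
        assert frequency_of_occurrence(scats, "amphipods") == pytest.approx(60.0)
        assert frequency_of_occurrence(scats, "herring_eggs") == 0.0
        assert frequency_of_occurrence(scats, "graminoids") == pytest.approx(40.0)

    def test_all_scats_contain_item(self):
        scats = [scat([{"seagrasses": 2.0}] * 5, scat_id=f"s{i}") for i in range(4)]
        assert frequency_of_occurrence(scats, "seagrasses") == 100.0


class TestFaecalVolume:
    def test_single_item_is_everything(self):
        assert faecal_volume([scat([{"graminoids": 2.0}] * 5)], "graminoids") == 100.0

    def test_equal_volumes_split_evenly(self):
        s = scat([{"graminoids": 2.0, "seagrasses": 2.0}] * 5)
        assert faecal_volume([s], "graminoids") == pytest.approx(50.0)

    def test_three_scat_hand_computed_shares(self):
        scats = [
            scat([{"graminoids": 4.0}] * 5, scat_id="a"),
            scat([{"graminoids": 1.0, "amphipods": 3.0}] * 5, scat_id="b"),
            scat([{"amphipods": 2.0}] * 5, scat_id="c"),
        ]
        fv = faecal_volume_table(scats)
        assert fv["graminoids"] == pytest.approx(100 * 5 / 10)
        assert fv["amphipods"] == pytest.approx(100 * 5 / 10)
        assert sum(fv.values()) == pytest.approx(100.0)


class TestCorrectionFactors:
    def test_single_included_item_is_100(self, diet_items):
        assert estimated_dietary_content({"herring_eggs": 12.0}, diet_items) == {
            "herring_eggs": 100.0
        }

    def test_published_2012_column_reproduced(self, diet_items, published_fv_2012):
        edc = estimated_dietary_content(published_fv_2012, diet_items)
        assert edc["herring_eggs"] == pytest.approx(62.7, abs=0.5)
        assert edc["amphipods"] == pytest.approx(8.3, abs=0.5)
        assert edc["seagrasses"] == pytest.approx(13.3, abs=0.5)
        assert edc["graminoids"] == pytest.approx(2.0, abs=0.5)
        edec = estimated_dietary_energy(edc, diet_items)
        assert edec["herring_eggs"] == pytest.approx(70.0, abs=0.5)
        assert edec["amphipods"] == pytest.approx(5.4, abs=0.5)
        assert edec["seagrasses"] == pytest.approx(13.3, abs=0.5)

    def test_scale_invariance(self, diet_items, published_fv_2012):
        doubled = {k: 2 * v for k, v in published_fv_2012.items()}
        assert estimated_dietary_content(doubled, diet_items) == pytest.approx(
            estimated_dietary_content(published_fv_2012, diet_items)
        )

    def test_excluded_items_dropped_silently(self, diet_items):
        edc = estimated_dietary_content({"herring_eggs": 1.0, "gravel": 50.0}, diet_items)
        assert "gravel" not in edc
        assert edc["herring_eggs"] == 100.0

    def test_undefined_item_with_positive_fv_raises(self, diet_items):
        with pytest.raises(ValueError, match="no definition"):
            estimated_dietary_content({"mystery_item": 3.0}, diet_items)

    def test_shared_cf2_makes_edec_equal_edc(self, diet_items):
        # brown and red algae share one cf2, so a two-item vector is unchanged
        edc = {"brown_algae": 60.0, "red_algae": 40.0}
        assert estimated_dietary_energy(edc, diet_items) == pytest.approx(edc)

    @given(
        vols=st.lists(
            st.floats(min_value=0.01, max_value=50.0), min_size=4, max_size=4
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_edc_round_trip_recovers_fv(self, diet_items, vols):
        items = ["herring_eggs", "amphipods", "graminoids", "seagrasses"]
        fv = dict(zip(items, vols))
        edc = estimated_dietary_content(fv, diet_items)
        back = {it: edc[it] / diet_items[it].cf1 for it in items}
        total = sum(back.values())
        fv_total = sum(fv.values())
        for it in items:
            assert back[it] / total == pytest.approx(fv[it] / fv_total, rel=1e-9)

    @given(
        vols=st.lists(st.floats(min_value=0.01, max_value=50.0), min_size=3, max_size=3)
    )
    @settings(deadline=None, max_examples=50)
    def test_edc_and_edec_sum_to_100(self, diet_items, vols):
        fv = dict(zip(["herring_eggs", "forbs", "brown_algae"], vols))
        edc = estimated_dietary_content(fv, diet_items)
        assert sum(edc.values()) == pytest.approx(100.0)
        assert sum(estimated_dietary_energy(edc, diet_items).values()) == pytest.approx(100.0)


class TestPerScatResponse:
    def test_egg_free_scats_give_zero(self, diet_items):
        scats = [scat([{"graminoids": 2.0}] * 5, scat_id=f"s{i}") for i in range(3)]
        out = egg_edc_by_site_date(scats, diet_items)
        assert (out["egg_edc"] == 0.0).all()

    def test_pure_egg_scat_is_100(self, diet_items):
        out = egg_edc_by_site_date([scat([{"herring_eggs": 4.0}] * 5)], diet_items)
        assert out["egg_edc"].item() == pytest.approx(100.0)

    def test_group_mean_of_per_scat_values(self, diet_items):
        s1 = scat([{"herring_eggs": 2.0, "graminoids": 2.0}] * 5, scat_id="a")
        s2 = scat([{"graminoids": 2.0}] * 5, scat_id="b")
        expected = (
            per_scat_edc(s1, diet_items)["herring_eggs"]
            + 0.0
        ) / 2
        out = egg_edc_by_site_date([s1, s2], diet_items)
        assert out["egg_edc"].item() == pytest.approx(expected)

    def test_inedible_only_scat_contributes_zero(self, diet_items):
        assert per_scat_edc(scat([{"gravel": 3.0}] * 5), diet_items) == {}


class TestSummaryTable:
    def test_render_and_group_additivity(self, diet_items):
        scats = [
            scat([{"herring_eggs": 2.0, "brown_algae": 1.0, "red_algae": 1.0}] * 5,
                 scat_id=f"s{i}")
            for i in range(4)
        ]
        table = render_summary({2012: scats}, diet_items)
        fv = table[("FV", 2012)]
        assert fv[[i for i in fv.index if not i.startswith("group:")]].sum() == pytest.approx(100.0)
        assert fv["group:macroalgae"] == pytest.approx(fv["brown_algae"] + fv["red_algae"])
        edc = table[("EDC", 2012)]
        included = ["herring_eggs", "brown_algae", "red_algae"]
        assert edc[included].sum() == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "value,rendered",
        [(0.4, "tr."), (0.49999, "tr."), (0.5, "0.5"), (0.0, "–"), (float("nan"), "–"), (12.34, "12.3")],
    )
    def test_display_threshold(self, value, rendered):
        assert format_display(value) == rendered
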