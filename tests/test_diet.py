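"""Diet compilation operations and landings reallocation."""

import numpy as np
import pandas as pd
import pytest

from trophos.diet import (
    DietError,
    DietSource,
    LandingsZoneTable,
    disaggregate_broad_prey,
    latitude_overlap,
    legacy_average,
    merge_sources,
    reallocate_landings,
    rescale_prey,
    species_to_group,
    standardize_diet,
)
from trophos.synth import SyntheticSpec, make_diet_sources


def diet_sum(d):
    return sum(d.values())


class TestStandardize:
    def test_unidentified_dropped(self):
        src = DietSource("x", 5, {"A": 30.0, "unidentified": 70.0})
        assert standardize_diet(src) == {"A": 1.0}

    def test_even_split(self):
        src = DietSource("x", 5, {"A": 2.0, "B": 2.0})
        assert standardize_diet(src) == {"A": 0.5, "B": 0.5}

    def test_fo_basis_treated_identically(self):
        w = DietSource("x", 5, {"A": 40.0, "B": 10.0}, basis="weight")
        fo = DietSource("x", 5, {"A": 40.0, "B": 10.0},
                        basis="frequency-of-occurrence")
        assert standardize_diet(w) == standardize_diet(fo)

    def test_all_unidentified_raises(self):
        with pytest.raises(DietError):
            standardize_diet(DietSource("x", 5, {"unid": 10.0}))


class TestMergeSources:
    def test_sample_size_weighting(self):
        s1 = DietSource("x", 30, {"X": 0.6, "Y": 0.4})
        s2 = DietSource("x", 10, {"X": 0.2, "Y": 0.8})
        merged = merge_sources([s1, s2])
        assert merged["X"] == pytest.approx(0.5)
        assert merged["Y"] == pytest.approx(0.5)

    def test_single_source_identity(self):
        s = DietSource("x", 12, {"X": 3.0, "Y": 1.0})
        assert merge_sources([s]) == pytest.approx({"X": 0.75, "Y": 0.25})

    def test_equal_diets_unchanged_by_n(self):
        s1 = DietSource("x", 3, {"X": 1.0, "Y": 1.0})
        s2 = DietSource("x", 300, {"X": 5.0, "Y": 5.0})
        assert merge_sources([s1, s2]) == pytest.approx({"X": 0.5, "Y": 0.5})

    def test_order_invariant(self):
        s1 = DietSource("x", 30, {"X": 0.6, "Y": 0.4})
        s2 = DietSource("x", 7, {"X": 0.1, "Y": 0.9})
        a = merge_sources([s1, s2])
        b = merge_sources([s2, s1])
        for k in a:
            assert a[k] == pytest.approx(b[k])


class TestSpeciesToGroup:
    def test_biomass_share_weighting(self):
        diets = {"harbor seal": {"fish": 1.0}, "fur seal": {"squid": 1.0}}
        combined = species_to_group(diets, {"harbor seal": 0.989, "fur seal": 0.011})
        assert combined["fish"] == pytest.approx(0.989)
        assert combined["squid"] == pytest.approx(0.011)

    def test_single_member_identity(self):
        d = {"only": {"A": 0.3, "B": 0.7}}
        assert species_to_group(d, {"only": 1.0}) == pytest.approx(d["only"])

    def test_normalization_preserved(self):
        diets = {"a": {"X": 0.5, "Y": 0.5}, "b": {"X": 0.9, "Z": 0.1}}
        out = species_to_group(diets, {"a": 0.25, "b": 0.75})
        assert diet_sum(out) == pytest.approx(1.0)


class TestDisaggregation:
    def test_proportional_split(self):
        out, warn = disaggregate_broad_prey(
            {"cephalopod": 0.2, "fish": 0.8},
            {"cephalopod": ["squid", "octopus"]},
            {"squid": 3.0, "octopus": 1.0},
            observed_prey={"squid", "octopus", "fish"},
        )
        assert warn == []
        assert out["squid"] == pytest.approx(0.15)
        assert out["octopus"] == pytest.approx(0.05)

    def test_unobserved_member_excluded(self):
        out, _ = disaggregate_broad_prey(
            {"cephalopod": 0.2, "fish": 0.8},
            {"cephalopod": ["squid", "octopus"]},
            {"squid": 3.0, "octopus": 1.0},
            observed_prey={"squid", "fish"},
        )
        assert out["squid"] == pytest.approx(0.2)
        assert "octopus" not in out

    def test_no_observed_member_warns_and_uses_all(self):
        out, warn = disaggregate_broad_prey(
            {"cephalopod": 1.0},
            {"cephalopod": ["squid", "octopus"]},
            {"squid": 1.0, "octopus": 1.0},
            observed_prey=set(),
        )
        assert warn
        assert out == pytest.approx({"squid": 0.5, "octopus": 0.5})

    def test_share_conserved(self):
        out, _ = disaggregate_broad_prey(
            {"broad": 0.6, "fish": 0.4},
            {"broad": ["a", "b", "c"]},
            {"a": 1.0, "b": 2.0, "c": 3.0},
            observed_prey={"a", "b", "c", "fish"},
        )
        assert diet_sum(out) == pytest.approx(1.0)


class TestRescaleAndLegacy:
    def test_salmon_rescale(self):
        out = rescale_prey({"salmon": 0.36, "other": 0.64}, "salmon", 0.20)
        assert out == pytest.approx({"salmon": 0.20, "other": 0.80})

    def test_identity_rescale(self):
        d = {"a": 0.3, "b": 0.7}
        assert rescale_prey(d, "a", 0.3) == pytest.approx(d)

    def test_untouched_ratios_preserved(self):
        out = rescale_prey({"a": 0.5, "b": 0.3, "c": 0.2}, "a", 0.1)
        assert out["b"] / out["c"] == pytest.approx(1.5)
        assert diet_sum(out) == pytest.approx(1.0)

    def test_legacy_average_identical(self):
        d = {"a": 0.4, "b": 0.6}
        assert legacy_average(d, dict(d)) == pytest.approx(d)

    def test_legacy_average_disjoint(self):
        out = legacy_average({"A": 1.0}, {"B": 1.0})
        assert out == pytest.approx({"A": 0.5, "B": 0.5})

    def test_legacy_average_normalized(self):
        out = legacy_average({"a": 0.2, "b": 0.8}, {"a": 1.0})
        assert diet_sum(out) == pytest.approx(1.0)


class TestPipelineNormalization:
    def test_columns_sum_to_one_at_every_stage(self):
        sources, _ = make_diet_sources(SyntheticSpec(seed=4))
        merged = merge_sources(sources)
        assert diet_sum(merged) == pytest.approx(1.0, abs=1e-9)
        grouped = species_to_group({"sp": merged}, {"sp": 1.0})
        assert diet_sum(grouped) == pytest.approx(1.0, abs=1e-9)
        disagg, _ = disaggregate_broad_prey(
            grouped, {"prey A": ["g1", "g2"]}, {"g1": 1.0, "g2": 2.0},
            observed_prey=set(grouped) | {"g1", "g2"},
        )
        assert diet_sum(disagg) == pytest.approx(1.0, abs=1e-9)


class TestLandingsReallocation:
    def zones(self):
        return LandingsZoneTable(pd.DataFrame({
            "lat_min": [42.0, 40.0],
            "lat_max": [46.0, 42.0],
            "group_id": [1, 1],
            "gear": ["trawl", "troll"],
            "landed_mt": [100.0, 40.0],
        }))

    def lat_bins(self):
        return {"south": (40.0, 44.4), "north": (44.4, 46.0)}

    def test_overlap_fraction(self):
        assert latitude_overlap((42.0, 46.0), (44.4, 46.0)) == pytest.approx(0.4)
        assert latitude_overlap((44.5, 45.0), (44.4, 46.0)) == 1.0
        assert latitude_overlap((30.0, 35.0), (44.4, 46.0)) == 0.0

    def test_total_weight_conserved(self):
        out = reallocate_landings(
            self.zones(), self.lat_bins(),
            {1: {"inner": 0.3, "mid": 0.7}},
            {"trawl": "trawl fleet", "troll": "troll fleet"},
        )
        assert out["landed_mt"].sum() == pytest.approx(140.0, abs=1e-9)

    def test_cross_shelf_proportions_applied(self):
        out = reallocate_landings(
            self.zones(), self.lat_bins(), {1: {"inner": 0.25, "outer": 0.75}},
            {"trawl": "f", "troll": "f"},
        )
        inner = out[out["subregion"].str.endswith("inner")]["landed_mt"].sum()
        assert inner == pytest.approx(0.25 * 140.0)

    def test_unmapped_gear_raises_with_names(self):
        with pytest.raises(DietError, match="troll"):
            reallocate_landings(self.zones(), self.lat_bins(), {},
                                {"trawl": "f"})

    def test_discard_rates_applied(self):
        rates = pd.DataFrame({"group_id": [1], "fleet": ["f"], "rate": [0.25]})
        out = reallocate_landings(
            self.zones(), self.lat_bins(), {}, {"trawl": "f", "troll": "f"},
            discard_rates=rates,
        )
        assert out["discard_mt"].sum() == pytest.approx(0.25 * 140.0)
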