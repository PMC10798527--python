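"""Delta-lognormal estimation and survey unit conversions."""

import math

import numpy as np
import pandas as pd
import pytest

from trophos.survey import (
    ConversionTables,
    SurveyError,
    apportion,
    arithmetic_mean_density,
    counts_to_biomass,
    delta_lognormal_mean,
    gelatinous_scaling,
    pennington_g,
    phyto_size_partition,
    seasonal_annual_mean,
    subregional_biomass,
    vgpm_to_phyto_biomass,
    volumetric_to_areal,
)
from trophos.synth import SyntheticSpec, make_survey


class TestDeltaLognormal:
    def test_all_zero_sample(self):
        assert delta_lognormal_mean([0.0, 0.0, 0.0]) == 0.0

    def test_degenerate_lognormal_equals_value(self):
        assert delta_lognormal_mean([5.0] * 8) == pytest.approx(5.0)

    def test_two_positives_no_variance(self):
        # [0, 0, e, e]: (2/4) e G_2(0) = e/2
        est = delta_lognormal_mean([0, 0, math.e, math.e])
        assert est == pytest.approx(math.e / 2, rel=1e-12)

    def test_single_positive(self):
        assert delta_lognormal_mean([0, 0, 0, 8.0]) == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(SurveyError):
            delta_lognormal_mean([1.0, -0.5])

    def test_g_series_at_zero_is_one(self):
        for m in (2, 5, 50):
            assert pennington_g(m, 0.0) == 1.0

    def test_unbiased_on_synthetic_delta_lognormal(self):
        """Mean of the estimator over replicates recovers
        p_pos exp(mu + sigma^2/2) within Monte-Carlo error."""
        spec0 = SyntheticSpec(zero_probability=0.4, log_mu=0.5, log_sigma=1.0,
                              n_hauls=1000)
        reps = 500
        ests = np.empty(reps)
        truth = None
        for r in range(reps):
            from dataclasses import replace
            df, truth = make_survey(replace(spec0, seed=r))
            ests[r] = delta_lognormal_mean(df["value"].to_numpy())
        se = ests.std(ddof=1) / math.sqrt(reps)
        assert abs(ests.mean() - truth) < 4 * se + 1e-3

    def test_lower_variance_than_arithmetic_on_heavy_tails(self):
        rng = np.random.default_rng(7)
        n, reps = 60, 400
        delta_est = np.empty(reps)
        arith_est = np.empty(reps)
        for r in range(reps):
            zero = rng.random(n) < 0.5
            x = np.where(zero, 0.0, rng.lognormal(0.0, 1.8, n))
            delta_est[r] = delta_lognormal_mean(x)
            arith_est[r] = arithmetic_mean_density(x)
        assert delta_est.var() < arith_est.var()


class TestConversions:
    def test_arithmetic_mean_with_zeros(self):
        assert arithmetic_mean_density([0, 0, 4]) == pytest.approx(4 / 3)

    @pytest.mark.parametrize("count, L, expected", [(0, 10, 0.0), (5, 10, 50.0)])
    def test_counts_to_biomass(self, count, L, expected):
        assert counts_to_biomass(count, L, (0.01, 3)) == pytest.approx(expected)

    def test_counts_linear_in_count(self):
        one = counts_to_biomass(1, 7.3, (0.02, 2.9))
        assert counts_to_biomass(10, 7.3, (0.02, 2.9)) == pytest.approx(10 * one)

    @pytest.mark.parametrize(
        "dens, depth, expected",
        [(1000.0, 100.0, 100.0), (5.0, 0.0, 0.0), (7.7, 1000.0, 7.7)],
    )
    def test_volumetric_to_areal(self, dens, depth, expected):
        assert volumetric_to_areal(dens, depth) == pytest.approx(expected)

    def test_conversions_homogeneous_degree_one(self):
        for f in (
            lambda v: volumetric_to_areal(v, 50.0),
            lambda v: gelatinous_scaling(v),
            lambda v: vgpm_to_phyto_biomass(v, 215.0),
        ):
            assert f(4.2) == pytest.approx(2.0 * f(2.1))

    def test_gelatinous_factor(self):
        assert gelatinous_scaling(1.0, 0.96, 0.80) == pytest.approx(0.2)
        assert gelatinous_scaling(3.0, 0.9, 0.9) == pytest.approx(3.0)

    def test_vgpm_division(self):
        assert vgpm_to_phyto_biomass(2150.0, 215.0) == pytest.approx(10.0)
        assert vgpm_to_phyto_biomass(0.0, 215.0) == 0.0


class TestSizePartition:
    def test_printed_coefficient_at_unit_chlorophyll(self):
        assert phyto_size_partition(1.0) == pytest.approx(0.30821, abs=1e-12)

    def test_power_law_at_high_chlorophyll(self):
        assert phyto_size_partition(10.0) == pytest.approx(
            0.30821 * 10 ** -0.82351, rel=1e-12
        )

    def test_clamped_at_low_chlorophyll(self):
        assert phyto_size_partition(0.1) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(SurveyError):
            phyto_size_partition(0.0)


class TestSeasonalMean:
    def test_constant_observations(self):
        assert seasonal_annual_mean([(10, 4.0), (200, 4.0)]) == pytest.approx(4.0)

    def test_single_observation(self):
        assert seasonal_annual_mean([(33, 2.5)]) == 2.5

    def test_antipodal_points_average(self):
        assert seasonal_annual_mean([(0, 2.0), (182.5, 4.0)]) == pytest.approx(
            3.0, abs=1e-2
        )


class TestApportionment:
    def test_krill_split_matches_reference_rows(self):
        """Aggregate krill 42.528 split by observed proportions gives the
        two species rows of the packaged parameter table."""
        parts = apportion(42.528, {"E. pacifica": 0.7594, "T. spinifera": 0.2406})
        assert parts["E. pacifica"] == pytest.approx(32.294, abs=2e-2)
        assert parts["T. spinifera"] == pytest.approx(10.234, abs=2e-2)


class TestSubregionalPipeline:
    def conv(self):
        return ConversionTables(pd.DataFrame({
            "species": ["a", "b"],
            "group_id": [1, 1],
            "estimator": ["arithmetic", "arithmetic"],
            "depth_m": [1000.0, 1000.0],
            "catchability": [1.0, 1.0],
        }))

    def records(self, rows):
        return pd.DataFrame(rows, columns=[
            "station_id", "subregion", "survey", "species", "value", "value_kind",
        ])

    def test_single_species_pipeline_composition(self):
        recs = self.records([(1, 1, "s1", "a", 2.0, "volumetric"),
                             (2, 1, "s1", "a", 4.0, "volumetric")])
        out, warn = subregional_biomass(recs, self.conv())
        assert warn == []
        assert out.loc[0, "biomass"] == pytest.approx(3.0)  # mean, 1 km depth

    def test_overlapping_surveys_averaged_then_summed(self):
        recs = self.records([
            (1, 1, "s1", "a", 2.0, "volumetric"),
            (1, 1, "s2", "a", 4.0, "volumetric"),
            (1, 1, "s1", "b", 1.0, "volumetric"),
        ])
        out, _ = subregional_biomass(recs, self.conv())
        # a: (2+4)/2 = 3; b: 1; group total 4
        assert out.loc[0, "biomass"] == pytest.approx(4.0)

    def test_unmapped_species_warns(self):
        recs = self.records([(1, 1, "s1", "zzz", 2.0, "volumetric")])
        out, warn = subregional_biomass(recs, self.conv())
        assert out.empty
        assert any("zzz" in w for w in warn)
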