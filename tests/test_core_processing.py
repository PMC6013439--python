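"""Core standardization: OM->OC conversion, carbon density, 10-cm
aggregation with the >50% terminal rule, and distribution fits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tidalcarbon import core_processing as cp
from tidalcarbon.synthetic_data import GeneratorConfig, generate_core_dataset

from conftest import brute_force_increments, random_core_samples


class TestOmToOc:
    def test_zero_om_clips_negative_constant_to_zero(self):
        assert cp.om_to_oc(0.0) == 0.0
        assert cp.om_to_oc(0.0, clip=False) == pytest.approx(-0.0080)

    def test_pure_organic_matter_default_coefficients(self):
        # 0.074 + 0.421 - 0.0080
        assert cp.om_to_oc(1.0) == pytest.approx(0.487, abs=1e-12)

    def test_pure_organic_matter_alternative_coefficients(self):
        assert cp.om_to_oc(1.0, coeffs=cp.OC_COEFFS_ALT) == pytest.approx(0.1081, abs=1e-12)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            cp.om_to_oc(1.2)
        with pytest.raises(ValueError):
            cp.om_to_oc(-0.1)

    def test_vectorized_and_nan_passthrough(self):
        out = cp.om_to_oc(np.array([0.0, 0.5, np.nan]))
        assert out.shape == (3,)
        assert np.isnan(out[2])


class TestCarbonDensity:
    def test_om_present_overrides_measured_oc(self):
        got = cp.compute_carbon_density(0.3, om_fraction=0.2, oc_fraction=0.5)
        assert got == pytest.approx(0.3 * cp.om_to_oc(0.2))

    def test_zero_bulk_density_gives_zero(self):
        assert cp.compute_carbon_density(0.0, om_fraction=0.4) == 0.0

    def test_measured_oc_used_when_om_absent(self):
        assert cp.compute_carbon_density(0.2, oc_fraction=0.10) == pytest.approx(0.020)

    def test_both_missing_signals_missing_not_error(self):
        assert math.isnan(cp.compute_carbon_density(0.5))

    def test_carbon_density_bounded_by_bulk_density(self):
        rng = np.random.default_rng(0)
        bd = rng.uniform(0, 2, 200)
        om = rng.uniform(0, 1, 200)
        cd = cp.compute_carbon_density(bd, om)
        assert np.all(cd >= 0)
        assert np.all(cd <= bd + 1e-12)


class TestAggregation:
    def test_depth_weighted_average_worked_example(self):
        samples = pd.DataFrame({
            "depth_top_cm": [0, 4], "depth_bottom_cm": [4, 12],
            "bulk_density_g_cm3": [0.2, 0.4],
            "om_fraction": [np.nan, np.nan], "oc_fraction": [np.nan, np.nan]})
        out = cp.aggregate_to_increments(samples)
        slab0 = out[out["increment_top"] == 0].iloc[0]
        assert slab0["bulk_density"] == pytest.approx((4 * 0.2 + 6 * 0.4) / 10)

    def test_single_exact_slab_is_identity(self):
        samples = pd.DataFrame({
            "depth_top_cm": [0], "depth_bottom_cm": [10],
            "bulk_density_g_cm3": [0.37], "om_fraction": [0.25],
            "oc_fraction": [np.nan]})
        out = cp.aggregate_to_increments(samples)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["bulk_density"] == pytest.approx(0.37)
        assert row["om_fraction"] == pytest.approx(0.25)
        assert row["coverage_cm"] == 10
        assert not row["extrapolated"]

    @pytest.mark.parametrize("bottom,populated", [(96, True), (95, False)])
    def test_terminal_extrapolation_majority_rule(self, bottom, populated):
        """>50% coverage (6 cm) extrapolates; exactly 50% (5 cm) is no-data."""
        samples = pd.DataFrame({
            "depth_top_cm": [0, 90], "depth_bottom_cm": [90, bottom],
            "bulk_density_g_cm3": [0.5, 0.8], "om_fraction": [0.1, 0.3],
            "oc_fraction": [np.nan, np.nan]})
        out = cp.aggregate_to_increments(samples)
        last = out[out["increment_top"] == 90]
        if populated:
            assert len(last) == 1
            assert last.iloc[0]["extrapolated"]
            assert last.iloc[0]["bulk_density"] == pytest.approx(0.8)
            assert last.iloc[0]["coverage_cm"] == bottom - 90
        else:
            assert len(last) == 0

    def test_overlapping_intervals_rejected(self):
        samples = pd.DataFrame({
            "depth_top_cm": [0, 5], "depth_bottom_cm": [8, 12],
            "bulk_density_g_cm3": [0.2, 0.3],
            "om_fraction": [0.1, 0.1], "oc_fraction": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="overlap"):
            cp.aggregate_to_increments(samples)

    def test_constant_profile_is_idempotent(self):
        samples = pd.DataFrame({
            "depth_top_cm": [0, 7, 20, 33], "depth_bottom_cm": [7, 20, 33, 50],
            "bulk_density_g_cm3": [0.42] * 4, "om_fraction": [0.3] * 4,
            "oc_fraction": [np.nan] * 4})
        out = cp.aggregate_to_increments(samples)
        np.testing.assert_allclose(out["bulk_density"], 0.42)
        np.testing.assert_allclose(out["om_fraction"], 0.3)

    def test_matches_brute_force_oracle_on_random_cores(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            samples = random_core_samples(rng)
            got = cp.aggregate_to_increments(samples).set_index("increment_top")
            want = brute_force_increments(samples).set_index("increment_top")
            assert list(got.index) == list(want.index)
            for col in ("bulk_density", "om_fraction", "oc_fraction"):
                np.testing.assert_allclose(got[col], want[col], atol=1e-12,
                                           err_msg=col)
            assert (got["coverage_cm"] == want["coverage_cm"]).all()
            assert (got["extrapolated"] == want["extrapolated"]).all()


class TestDistributionFit:
    def test_standard_error_of_reported_summary(self):
        assert cp.standard_error(0.013, 8280) == pytest.approx(1.4e-4, abs=5e-6)

    def test_truncated_normal_parameter_recovery(self):
        mu, sigma = 0.027, 0.013
        a = (0 - mu) / sigma
        x = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=100_000,
                                random_state=np.random.default_rng(5))
        fit = cp.fit_carbon_distribution(x, "truncated_normal")
        assert fit.family == "truncated_normal"
        assert abs(fit.loc - mu) < 3 * sigma / math.sqrt(len(x)) * 2
        assert abs(fit.scale - sigma) < 0.001
        assert fit.se == pytest.approx(fit.sd / math.sqrt(fit.n))

    def test_lognormal_zero_recast(self):
        vals = np.array([0.0, 0.01, 0.02, 0.03, 0.05])
        fit = cp.fit_carbon_distribution(vals, "log_normal")
        recast = np.where(vals == 0, 1e-5, vals)
        logx = np.log(recast)
        want_ll = float(np.sum(stats.lognorm.logpdf(
            recast, s=logx.std(), scale=math.exp(logx.mean()))))
        assert fit.log_likelihood == pytest.approx(want_ll)

    def test_truncated_normal_beats_lognormal_on_symmetric_data(self):
        rng = np.random.default_rng(17)
        x = np.clip(rng.normal(0.027, 0.013, 20_000), 0, None)
        tn = cp.fit_carbon_distribution(x, "truncated_normal")
        ln = cp.fit_carbon_distribution(x, "log_normal")
        assert tn.log_likelihood > ln.log_likelihood

    def test_degenerate_input_rejected(self):
        with pytest.raises(cp.DegenerateFitError):
            cp.fit_carbon_distribution([0.02] * 10)
        with pytest.raises(ValueError):
            cp.fit_carbon_distribution([0.02])
        with pytest.raises(ValueError):
            cp.fit_carbon_distribution([0.02, 0.03], family="gamma")


class TestDepthProfiles:
    def test_single_record_has_missing_se(self):
        inc = pd.DataFrame({"increment_top": [0], "bulk_density": [0.5],
                            "om_fraction": [0.2], "carbon_density": [0.02]})
        out = cp.summarize_depth_profiles(inc)
        assert out.loc[0, "carbon_density_n"] == 1
        assert np.isnan(out.loc[0, "carbon_density_se"])

    def test_identical_records_have_zero_se(self):
        inc = pd.DataFrame({"increment_top": [0] * 5, "bulk_density": [0.5] * 5,
                            "om_fraction": [0.2] * 5, "carbon_density": [0.02] * 5})
        out = cp.summarize_depth_profiles(inc)
        assert out.loc[0, "carbon_density_se"] == 0.0

    def test_generator_depth_structure_is_preserved(self):
        """BD decreasing / OM increasing with depth by construction survives
        the summary."""
        rows = []
        for top in range(0, 100, 10):
            for i in range(4):
                rows.append({"increment_top": top,
                             "bulk_density": 1.0 - 0.005 * top + 0.01 * i,
                             "om_fraction": 0.1 + 0.002 * top + 0.005 * i,
                             "carbon_density": 0.02})
        out = cp.summarize_depth_profiles(pd.DataFrame(rows))
        assert (np.diff(out["bd_mean"]) < 0).all()
        assert (np.diff(out["om_mean"]) > 0).all()
        assert list(out["increment_top"]) == list(range(0, 100, 10))
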