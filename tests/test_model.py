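"""Ecometric model core: binning, kernel likelihood peaks, estimation
rules, fit statistics, anomalies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecometrics import EcometricModel, bin_communities, evaluate_fit, fit_bin_likelihood
from ecometrics.model import DegenerateAxisError, silverman_bandwidth


def brute_force_assign(mean, sd, space):
    """Linear search over all bin rectangles (half-open, last closed)."""
    out = []
    for m, s in zip(mean, sd):
        hit = None
        for i in range(space.n_bins):
            for j in range(space.n_bins):
                lo_m, hi_m = space.mean_edges[i], space.mean_edges[i + 1]
                lo_s, hi_s = space.sd_edges[j], space.sd_edges[j + 1]
                in_m = (lo_m <= m < hi_m) or (i == space.n_bins - 1 and lo_m <= m <= hi_m)
                in_s = (lo_s <= s < hi_s) or (j == space.n_bins - 1 and lo_s <= s <= hi_s)
                if in_m and in_s:
                    hit = (i, j)
        out.append(hit)
    return out


class TestBinning:
    def test_default_space_has_625_bins(self, random_summaries):
        space, _, _ = bin_communities(
            random_summaries["trait_mean"], random_summaries["trait_sd"], n_bins=25
        )
        assert space.n_total_bins == 625

    def test_extremes_land_in_corner_bins(self):
        mean = np.array([0.5, 0.6, 0.9])
        sd = np.array([0.01, 0.1, 0.2])
        space, i, j = bin_communities(mean, sd, n_bins=25)
        assert (i[0], j[0]) == (0, 0)
        assert (i[2], j[2]) == (24, 24)

    def test_interior_edge_maps_to_higher_bin(self):
        space, i, j = bin_communities([0.0, 1.0, 0.5], [0.0, 1.0, 0.5], n_bins=2)
        assert i[2] == 1 and j[2] == 1  # value exactly on the interior edge

    def test_assignment_matches_brute_force_and_partitions(self):
        rng = np.random.default_rng(23)
        mean = rng.uniform(0.4, 1.0, 1000)
        sd = rng.uniform(0.0, 0.3, 1000)
        space, i, j = bin_communities(mean, sd, n_bins=25)
        expected = brute_force_assign(mean, sd, space)
        assert all(e is not None for e in expected)
        assert list(zip(i, j)) == expected
        # conservation: bin counts sum to n, one bin per community
        counts = np.zeros((25, 25), int)
        np.add.at(counts, (i, j), 1)
        assert counts.sum() == 1000

    def test_degenerate_axis_is_informative_error(self):
        with pytest.raises(DegenerateAxisError, match="zero width"):
            bin_communities([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


class TestBinLikelihood:
    def test_identical_values_peak_at_that_value(self):
        _, _, peak, _ = fit_bin_likelihood([7.5, 7.5, 7.5], bandwidth=1.0)
        assert peak == pytest.approx(7.5, abs=0.1)

    def test_symmetric_bimodal_tie_breaks_to_smaller_value(self):
        grid, dens, peak, _ = fit_bin_likelihood([0.0, 0.0, 10.0, 10.0], bandwidth=0.5)
        # two equal maxima by symmetry; the documented tie-break picks 0
        assert abs(peak) < 0.5
        mirror = dens[::-1]
        np.testing.assert_allclose(dens, mirror, rtol=1e-9)

    def test_gaussian_sample_peak_near_true_mode(self):
        # repeat-sampling: the average peak over fresh draws recovers the
        # known mode; any single sample's mode estimate is noisier
        rng = np.random.default_rng(6)
        peaks = [
            fit_bin_likelihood(rng.normal(10.0, 1.0, 500), bandwidth="auto")[2]
            for _ in range(20)
        ]
        assert np.mean(peaks) == pytest.approx(10.0, abs=0.2)
        assert all(abs(p - 10.0) < 1.0 for p in peaks)

    def test_empty_bin_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            fit_bin_likelihood([])

    def test_peak_matches_finer_grid_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            vals = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 2), rng.integers(2, 20))
            h = float(rng.uniform(0.2, 1.5))
            _, _, peak, _ = fit_bin_likelihood(vals, bandwidth=h)
            fine = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, 5120)
            dens = np.exp(-0.5 * ((fine[:, None] - vals[None, :]) / h) ** 2).sum(axis=1)
            assert abs(peak - fine[np.argmax(dens)]) <= h / 10

    def test_large_bandwidth_peak_approaches_sample_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 10, 25)
        h = 1000.0
        grid, _, peak, _ = fit_bin_likelihood(vals, bandwidth=h)
        step = grid[1] - grid[0]
        assert abs(peak - vals.mean()) <= step

    def test_silverman_bandwidth_matches_rule(self):
        v = np.arange(10.0)
        expected = 0.9 * min(v.std(ddof=1), (np.percentile(v, 75) - np.percentile(v, 25)) / 1.34) * 10 ** (-0.2)
        assert silverman_bandwidth(v) == pytest.approx(expected)


class TestEvaluateFit:
    def test_perfect_agreement_is_one(self):
        v = np.linspace(0, 5, 50)
        assert evaluate_fit(v, v) == pytest.approx(1.0)

    def test_constant_estimates_define_zero(self):
        assert evaluate_fit(np.full(10, 3.0), np.arange(10.0)) == 0.0

    def test_permuted_perfect_estimates_lose_association(self):
        rng = np.random.default_rng(8)
        obs = rng.normal(size=1000)
        assert evaluate_fit(rng.permutation(obs), obs) < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_fit([1.0, 2.0], [1.0, 2.0])


class TestFittedModel:
    def test_round_trip_estimate_equals_own_bin_peak(self, random_summaries):
        res = EcometricModel(random_summaries, env="MAT").fit()
        np.testing.assert_array_equal(
            res.estimates, res.peaks[res.bin_i, res.bin_j]
        )
        assert np.all(~np.isnan(res.estimates))

    def test_membership_partitions_communities(self, random_summaries):
        res = EcometricModel(random_summaries, env="MAT").fit()
        assert res.counts.sum() == len(random_summaries)

    def test_disjoint_cold_hot_bins_order_their_estimates(self):
        n = 40
        cold = pd.DataFrame(
            {"trait_mean": np.linspace(0.55, 0.6, n), "trait_sd": np.full(n, 0.05),
             "mat": np.random.default_rng(0).normal(-5, 1, n)}
        )
        hot = pd.DataFrame(
            {"trait_mean": np.linspace(0.85, 0.9, n), "trait_sd": np.full(n, 0.2),
             "mat": np.random.default_rng(1).normal(25, 1, n)}
        )
        summ = pd.concat([cold, hot], ignore_index=True)
        res = EcometricModel(summ, env="MAT", n_bins=2).fit()
        assert res.estimates[:n].max() < res.estimates[n:].min()

    def test_ap_is_fitted_on_log_scale_and_reported_in_mm(self, random_summaries):
        res = EcometricModel(random_summaries, env="AP").fit()
        # model-scale estimates are ln(mm); natural-scale are mm
        np.testing.assert_allclose(res.estimates_natural, np.exp(res.estimates))
        np.testing.assert_allclose(
            res.anomalies, np.exp(res.estimates) - random_summaries["ap"]
        )

    def test_anomaly_sign_convention(self, random_summaries):
        res = EcometricModel(random_summaries, env="MAT").fit()
        np.testing.assert_allclose(
            res.anomalies, res.estimates - random_summaries["mat"]
        )

    def test_predict_on_training_point_round_trips(self, random_summaries):
        res = EcometricModel(random_summaries, env="MAT").fit()
        k = 17
        est = res.predict(
            random_summaries["trait_mean"].iloc[k], random_summaries["trait_sd"].iloc[k]
        )
        assert est == res.estimates[k]

    def test_out_of_range_summary_clamps_with_flag(self, random_summaries):
        res = EcometricModel(random_summaries, env="MAT").fit()
        est, clamped, _ = res.predict(2.0, 0.9, return_flags=True)
        assert clamped
        assert np.isfinite(est)

    def test_empty_bin_borrows_nearest_nonempty(self):
        # two clusters leave the middle of the space empty
        rng = np.random.default_rng(4)
        n = 30
        summ = pd.DataFrame(
            {
                "trait_mean": np.r_[rng.uniform(0.5, 0.55, n), rng.uniform(0.9, 0.95, n)],
                "trait_sd": np.r_[rng.uniform(0.01, 0.03, n), rng.uniform(0.2, 0.22, n)],
                "mat": np.r_[rng.normal(0, 1, n), rng.normal(20, 1, n)],
            }
        )
        res = EcometricModel(summ, env="MAT", n_bins=25).fit()
        mid_mean, mid_sd = 0.72, 0.11
        est, clamped, borrowed = res.predict(mid_mean, mid_sd, return_flags=True)
        assert borrowed and not clamped
        assert np.isfinite(est)

    def test_summary_text_reports_key_quantities(self, random_summaries):
        res = EcometricModel(random_summaries, env="AP").fit()
        text = res.summary()
        assert "625" in text and "R^2" in text and "AP" in text

    def test_r_squared_between_zero_and_one(self, random_summaries):
        for env in ("MAT", "AP"):
            r2 = EcometricModel(random_summaries, env=env).fit().r_squared
            assert 0.0 <= r2 <= 1.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15, derandomize=True, deadline=None)
def test_binning_partition_property(seed):
    """Every community lands in exactly one bin; counts conserve."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    mean = rng.uniform(0.4, 1.0, n)
    sd = rng.uniform(0.0, 0.3, n)
    if np.ptp(mean) == 0 or np.ptp(sd) == 0:
        return
    space, i, j = bin_communities(mean, sd, n_bins=10)
    assert i.shape == (n,)
    assert ((0 <= i) & (i < 10)).all() and ((0 <= j) & (j < 10)).all()
    counts = np.zeros((10, 10), int)
    np.add.at(counts, (i, j), 1)
    assert counts.sum() == n
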