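"""Adaptive weighted average and weighted-median consensus estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kctree.consistency import dersimonian_laird_tau, weighted_mean
from kctree.freq import (
    adaptive_weighted_average,
    weighted_median_consensus,
    weighted_median_point,
)

from .conftest import make_study


class TestAdaptiveWeightedAverage:
    def test_k45_printed_kcrv(self, k45):
        res = adaptive_weighted_average(k45, seed=1)
        assert res.kcrv == pytest.approx(226.5, abs=0.1)
        assert res.details["internal_std_unc"] == pytest.approx(0.5, abs=0.02)

    def test_collapses_to_weighted_mean_when_tau_zero(self):
        s = make_study([10.0, 10.01, 9.99], [0.5, 0.5, 0.5])
        assert dersimonian_laird_tau(s).tau_hat == 0.0
        res = adaptive_weighted_average(s, n_boot=200, seed=1)
        assert res.kcrv == weighted_mean(s).estimate

    def test_bootstrap_sd_matches_internal_when_tau_zero(self):
        # all dof infinite, tau_hat = 0: the bootstrap must reproduce the
        # closed-form fixed-effects uncertainty within 5 %
        s = make_study([10.0, 10.02, 9.99, 10.01], [0.5, 0.4, 0.6, 0.5])
        assert dersimonian_laird_tau(s).tau_hat == 0.0
        res = adaptive_weighted_average(s, n_boot=50000, seed=2)
        internal = weighted_mean(s).internal_std_unc
        assert res.details["bootstrap_std_unc"] == pytest.approx(internal, rel=0.05)

    def test_reproducible_given_seed(self, k45):
        a = adaptive_weighted_average(k45, n_boot=500, seed=3)
        b = adaptive_weighted_average(k45, n_boot=500, seed=3)
        assert a.std_unc == b.std_unc
        assert np.array_equal(a.draws["mu"], b.draws["mu"])

    def test_draws_center_on_kcrv(self, k45):
        res = adaptive_weighted_average(k45, n_boot=5000, seed=4)
        mc_se = res.draws["mu"].std() / np.sqrt(len(res.draws["mu"]))
        assert abs(res.draws["mu"].mean() - res.kcrv) < 3 * mc_se

    def test_location_scale_equivariance(self, k45):
        a, c = 7.5, 3.0
        x, u, nu = k45.arrays(included_only=False)
        scaled = make_study(
            a + c * x, c * u, dof=list(nu),
            include=[r.include_in_kcrv for r in k45.results],
        )
        r0 = adaptive_weighted_average(k45, n_boot=2000, seed=5)
        r1 = adaptive_weighted_average(scaled, n_boot=2000, seed=5)
        assert r1.kcrv == pytest.approx(a + c * r0.kcrv, rel=1e-9)
        assert r1.std_unc == pytest.approx(c * r0.std_unc, rel=1e-9)


class TestWeightedMedianPoint:
    def test_equal_weights_odd_n_is_sample_median(self):
        x = [3.0, 1.0, 2.0, 9.0, 5.0]
        assert weighted_median_point(x, np.ones(5)) == 3.0

    def test_dominant_first_weight(self):
        assert weighted_median_point([1.0, 2.0, 10.0], [0.6, 0.2, 0.2]) == 1.0

    def test_exact_half_interpolates_midpoint(self):
        assert weighted_median_point([1.0, 3.0], [0.5, 0.5]) == 2.0

    def test_grid_minimization_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(0, 1, 7)
            w = rng.uniform(0.1, 2.0, 7)
            grid = np.linspace(x.min(), x.max(), 40001)
            obj = (w[:, None] * np.abs(x[:, None] - grid)).sum(axis=0)
            oracle = grid[np.argmin(obj)]
            assert weighted_median_point(x, w) == pytest.approx(
                oracle, abs=2 * (x.max() - x.min()) / 40000
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_median_point([], [])

    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_equivariance(self, shift, scale):
        x = np.array([1.0, 4.0, 2.0, 8.0, 3.0])
        w = np.array([0.2, 0.5, 1.0, 0.1, 0.7])
        m = weighted_median_point(x, w)
        assert weighted_median_point(shift + scale * x, w) == pytest.approx(
            shift + scale * m, rel=1e-9, abs=1e-9
        )

    def test_resistance_to_outlier_growth(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        w = np.ones(5)
        m = weighted_median_point(x, w)
        x2 = x.copy()
        x2[-1] = 1e9
        assert weighted_median_point(x2, w) == m


class TestWeightedMedianConsensus:
    def test_k145_zn_printed_values(self, k145_zn):
        res = weighted_median_consensus(k145_zn, n_boot=5000, seed=1)
        assert res.details["bootstrap"] == "nonparametric"
        assert res.kcrv == pytest.approx(457.55, abs=0.5)
        assert res.std_unc == pytest.approx(1.65, abs=0.15)

    def test_within_data_range(self, k145_zn):
        res = weighted_median_consensus(k145_zn, n_boot=2000, seed=2)
        x, _, _ = k145_zn.arrays()
        assert x.min() <= res.kcrv <= x.max()

    def test_auto_uses_parametric_for_small_n(self, toy_study):
        res = weighted_median_consensus(toy_study, n_boot=1000, seed=1)
        assert res.details["bootstrap"] == "parametric"

    def test_symmetric_study_negligible_bias_correction(self):
        s = make_study([-2.0, -1.0, 0.0, 1.0, 2.0], [0.5] * 5)
        res = weighted_median_consensus(
            s, n_boot=20000, seed=3, bootstrap="parametric"
        )
        assert abs(res.details["bias_correction"]) < 0.02

    def test_reproducible_given_seed(self, k145_zn):
        a = weighted_median_consensus(k145_zn, n_boot=500, seed=9)
        b = weighted_median_consensus(k145_zn, n_boot=500, seed=9)
        assert a.kcrv == b.kcrv
        assert np.array_equal(a.draws["mu"], b.draws["mu"])

    def test_location_scale_equivariance(self, k145_zn):
        a, c = -3.0, 2.5
        x, u, _ = k145_zn.arrays(included_only=False)
        scaled = make_study(
            a + c * x, c * u,
            include=[r.include_in_kcrv for r in k145_zn.results],
        )
        r0 = weighted_median_consensus(k145_zn, n_boot=2000, seed=7)
        r1 = weighted_median_consensus(scaled, n_boot=2000, seed=7)
        assert r1.kcrv == pytest.approx(a + c * r0.kcrv, rel=1e-9)
        assert r1.std_unc == pytest.approx(c * r0.std_unc, rel=1e-9)

    def test_nonparametric_needs_five(self):
        s = make_study([1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            weighted_median_consensus(s, bootstrap="nonparametric", seed=1)
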