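"""Feature vectors, Mahalanobis distances, Hotelling significance, border calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cortexmap as cm
from cortexmap.borders import (_local_maxima, blocksize_sweep,
                               cross_section_consistency, feature_matrix,
                               hotelling_p, mahalanobis_d2, md_trace,
                               profile_features)


def brute_force_features(values, grid=None):
    """Direct-summation oracle for the 10 moment features."""
    values = np.asarray(values, float)
    if grid is None:
        grid = np.linspace(0.0, 100.0, values.size)

    def five(w, g):
        amp = sum(w) / len(w)
        tot = sum(w)
        if tot == 0:
            return [amp, (g[0] + g[-1]) / 2, 0.0, 0.0, 0.0]
        c = sum(wi * gi for wi, gi in zip(w, g)) / tot
        var = sum(wi * (gi - c) ** 2 for wi, gi in zip(w, g)) / tot
        disp = var ** 0.5
        if disp == 0:
            return [amp, c, 0.0, 0.0, 0.0]
        skew = sum(wi * ((gi - c) / disp) ** 3 for wi, gi in zip(w, g)) / tot
        kurt = sum(wi * ((gi - c) / disp) ** 4 for wi, gi in zip(w, g)) / tot - 3.0
        return [amp, c, disp, skew, kurt]

    d = [abs(values[i + 1] - values[i]) for i in range(len(values) - 1)]
    dg = [(grid[i] + grid[i + 1]) / 2 for i in range(len(grid) - 1)]
    return np.array(five(list(values), list(grid)) + five(d, dg))


class TestProfileFeatures:
    def test_constant_profile_centroid_and_symmetry(self):
        f = profile_features(np.full(101, 0.5)).values
        assert f[1] == pytest.approx(50.0)
        assert f[3] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_triangle_centroid_and_zero_skew(self):
        grid = np.linspace(0, 100, 101)
        tri = 1.0 - np.abs(grid - 50.0) / 50.0
        f = profile_features(tri).values
        assert f[1] == pytest.approx(50.0)
        assert f[3] == pytest.approx(0.0, abs=1e-10)

    def test_all_ten_features_match_direct_summation_oracle(self, rng):
        for _ in range(5):
            v = rng.random(41) * 0.8
            got = profile_features(v).values
            want = brute_force_features(v)
            assert np.max(np.abs(got - want)) < 1e-10

    def test_vectorized_feature_matrix_equals_per_profile_path(self, rng):
        m = rng.random((20, 31))
        fm = feature_matrix(m)
        for i in range(20):
            assert np.allclose(fm[i], profile_features(m[i]).values, atol=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            profile_features(np.array([0.1, -0.2, 0.3]))

    def test_all_zero_profile_degenerate_sentinel_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            f = profile_features(np.zeros(11)).values
        assert np.allclose(f, [0, 50, 0, 0, 0, 0, 50, 0, 0, 0])


class TestMahalanobis:
    def test_identical_blocks_give_zero(self, rng):
        a = rng.normal(size=(8, 4))
        assert mahalanobis_d2(a, a.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_two_feature_toy_blocks_match_hand_computation(self):
        a = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0]])
        b = np.array([[4.0, 1.0], [5.0, 2.0], [6.0, 3.0]])
        # explicit matrix arithmetic with the analytic 2x2 inverse
        ma, mb = a.mean(0), b.mean(0)
        sa = (a - ma).T @ (a - ma) / 2
        sb = (b - mb).T @ (b - mb) / 2
        s = (2 * sa + 2 * sb) / 4
        det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
        sinv = np.array([[s[1, 1], -s[0, 1]], [-s[1, 0], s[0, 0]]]) / det
        d = ma - mb
        expected = float(d @ sinv @ d)
        assert mahalanobis_d2(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=(9, 5)), rng.normal(size=(11, 5))
        assert mahalanobis_d2(a, b) == pytest.approx(mahalanobis_d2(b, a))

    def test_affine_invariance_of_feature_units(self, rng):
        a, b = rng.normal(size=(15, 6)), rng.normal(size=(15, 6))
        t = rng.normal(size=(6, 6)) + 3 * np.eye(6)   # well-conditioned affine map
        shift = rng.normal(size=6)
        d_raw = mahalanobis_d2(a, b)
        d_aff = mahalanobis_d2(a @ t + shift, b @ t + shift)
        assert d_aff == pytest.approx(d_raw, rel=1e-6)

    def test_singular_covariance_without_regularization_raises(self):
        a = np.tile([1.0, 2.0, 3.0], (5, 1))
        b = np.tile([2.0, 2.0, 3.0], (5, 1))
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            mahalanobis_d2(a, b, regularize=False)

    def test_nonnegative_on_random_blocks(self, rng):
        for _ in range(20):
            a = rng.normal(size=(12, 10))
            b = rng.normal(size=(12, 10))
            assert mahalanobis_d2(a, b) >= 0.0


class TestHotelling:
    def test_zero_distance_gives_p_one(self):
        assert hotelling_p(0.0, 16, 16, 10) == pytest.approx(1.0)

    def test_univariate_reduction_matches_t_test(self, rng):
        for _ in range(10):
            a = rng.normal(size=(12, 1))
            b = rng.normal(0.4, 1.0, size=(15, 1))
            p = hotelling_p(mahalanobis_d2(a, b), 12, 15, 1)
            p_t = stats.ttest_ind(a.ravel(), b.ravel()).pvalue
            assert p == pytest.approx(p_t, abs=1e-10)

    def test_insufficient_degrees_of_freedom_raises(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            hotelling_p(1.0, 5, 5, 10)

    def test_monotone_decreasing_in_distance(self):
        ps = [hotelling_p(d2, 16, 16, 10) for d2 in (0.1, 1.0, 5.0, 20.0)]
        assert all(x > y for x, y in zip(ps, ps[1:]))


class TestMDTrace:
    def test_constant_profiles_give_identically_zero_trace(self):
        m = np.tile(np.linspace(0.2, 0.6, 51), (60, 1))
        trace = md_trace(feature_matrix(m), 16)
        assert np.allclose(trace.d2, 0.0)
        assert trace.maxima.size == 0

    def test_positions_and_bonferroni_family_size(self):
        feats = np.random.default_rng(0).normal(size=(200, 10)) + 5.0
        trace = md_trace(feats, 16, alpha=0.01)
        assert trace.positions[0] == 16 and trace.positions[-1] == 184
        assert trace.positions.size == 200 - 32 + 1
        assert np.allclose(np.minimum(trace.p * trace.positions.size, 1.0),
                           trace.p_adjusted)

    def test_two_area_border_recovered_within_tolerance(self):
        m, truth = cm.generate_ribbon(cm.two_area_spec(seed=42))
        trace = md_trace(feature_matrix(m), 16)
        assert trace.maxima.size >= 1
        best = trace.maxima[np.argmax(trace.d2[np.searchsorted(trace.positions,
                                                               trace.maxima)])]
        assert abs(best - truth[0]) <= 3

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError, match="2\\*block_size"):
            md_trace(np.zeros((20, 10)), 16)

    def test_local_maxima_plateau_takes_leftmost(self):
        y = np.array([0.0, 1.0, 1.0, 1.0, 0.0, 2.0, 0.0])
        assert _local_maxima(y).tolist() == [1, 5]


class TestBlocksizeSweep:
    def test_two_area_single_consensus_call(self):
        m, truth = cm.generate_ribbon(cm.two_area_spec(seed=3))
        calls = blocksize_sweep(feature_matrix(m))
        assert len(calls) == 1
        assert abs(calls[0].position - truth[0]) <= 3
        assert len(calls[0].supporting_block_sizes) >= 0.6 * 15

    def test_three_area_ribbon_two_calls(self):
        from cortexmap.synthetic import gli_template
        a = gli_template([(30.0, 0.5, 12.0)])
        b = gli_template([(55.0, 0.5, 12.0)])
        c = gli_template([(75.0, 0.5, 10.0)])
        spec = cm.RibbonSpec(210, 101, [("A", a), ("B", b), ("C", c)],
                             [70, 140], noise_sd=0.02, seed=5)
        calls = blocksize_sweep(feature_matrix(cm.generate_ribbon(spec)[0]))
        assert len(calls) == 2
        assert abs(calls[0].position - 70) <= 3
        assert abs(calls[1].position - 140) <= 3

    def test_exact_recovery_at_zero_noise(self):
        m, truth = cm.generate_ribbon(cm.two_area_spec(noise_sd=0.0))
        calls = blocksize_sweep(feature_matrix(m))
        assert len(calls) == 1
        assert calls[0].position == truth[0]

    def test_homogeneous_ribbons_rarely_call_borders(self):
        n_called = 0
        for seed in range(15):
            m, _ = cm.generate_ribbon(cm.homogeneous_spec(seed=900 + seed))
            n_called += bool(blocksize_sweep(feature_matrix(m)))
        assert n_called == 0

    def test_alpha_zero_calls_nothing(self):
        m, _ = cm.generate_ribbon(cm.two_area_spec(seed=3))
        assert blocksize_sweep(feature_matrix(m), alpha=0.0) == []

    def test_separation_monotonicity_of_border_distance(self):
        # stronger laminar contrast never lowers D^2 at the true border
        d2_at_border = []
        for sep in (1.0, 2.0, 3.0, 4.0):
            spec = cm.two_area_spec(separation=sep, seed=11)
            m, _ = cm.generate_ribbon(spec)
            trace = md_trace(feature_matrix(m), 16)
            d2_at_border.append(trace.d2[np.searchsorted(trace.positions, 100)])
        assert all(x <= y + 1e-9 for x, y in zip(d2_at_border, d2_at_border[1:]))


class TestCrossSectionConsistency:
    def _call(self, pos):
        return cm.BorderCall(pos, (10, 12), 1e-4)

    def test_identical_sections_all_confirmed(self):
        calls = [[self._call(50.0), self._call(120.0)] for _ in range(3)]
        confirmed, unconfirmed = cross_section_consistency(calls)
        assert len(confirmed) == 2 and not unconfirmed
        assert all(c.n_sections == 3 for c in confirmed)

    def test_call_in_single_section_reported_unconfirmed(self):
        calls = [[self._call(50.0)], [], []]
        confirmed, unconfirmed = cross_section_consistency(calls)
        assert not confirmed
        assert len(unconfirmed) == 1 and unconfirmed[0].position == 50.0

    def test_jittered_calls_confirmed_at_median(self):
        calls = [[self._call(49.0)], [self._call(50.0)], [self._call(52.0)]]
        confirmed, _ = cross_section_consistency(calls, tol=3.0)
        assert len(confirmed) == 1
        assert confirmed[0].position == 50.0

    def test_requires_at_least_two_sections(self):
        with pytest.raises(ValueError, match="two sections"):
            cross_section_consistency([[self._call(5.0)]])


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_d2_affine_invariance_property(seed):
    """Mahalanobis distance is invariant under invertible affine feature maps."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(14, 4))
    b = rng.normal(1.0, 1.0, size=(14, 4))
    t = rng.normal(size=(4, 4)) + 4 * np.eye(4)
    assert mahalanobis_d2(a @ t, b @ t) == pytest.approx(
        mahalanobis_d2(a, b), rel=1e-5)
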