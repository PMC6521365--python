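"""Fast-MCD estimation, outlyingness, thresholds and corr-max partitions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from cohortqc.mcd import (DegenerateSubsetError, c_step, compute_h,
                          consistency_factor, corr_max_contributions,
                          detect_mcd, fast_mcd, mahalanobis_distances,
                          outlyingness, simulate_threshold)
from conftest import make_prepared, standardized


def brute_force_min_det(X, h):
    """Exhaustive MCD oracle: minimal ML-covariance determinant over h-subsets."""
    best = np.inf
    for subset in itertools.combinations(range(X.shape[0]), h):
        sub = X[list(subset)]
        centered = sub - sub.mean(axis=0)
        det = np.linalg.det(centered.T @ centered / h)
        best = min(best, det)
    return best


class TestComputeH:
    @pytest.mark.parametrize("n,p,alpha,expected", [
        (161, 53, 0.8, 139),
        (148, 29, 0.8, 124),
    ])
    def test_reference_values(self, n, p, alpha, expected):
        assert compute_h(n, p, alpha) == expected

    @given(n=st.integers(10, 500), p=st.integers(1, 9))
    @settings(max_examples=50, derandomize=True)
    def test_boundary_alphas_and_range(self, n, p):
        m = (n + p + 1) // 2
        assert compute_h(n, p, 1.0) == n
        assert compute_h(n, p, 0.5) == m
        for alpha in (0.6, 0.75, 0.9):
            assert m <= compute_h(n, p, alpha) <= n

    def test_rejects_wide_data(self):
        with pytest.raises(ValueError, match="more observations than variables"):
            compute_h(5, 6, 0.8)


class TestMahalanobis:
    def test_center_is_zero(self):
        mu = np.array([1.0, -2.0])
        assert mahalanobis_distances(mu, mu, np.eye(2))[0] == 0.0

    def test_identity_covariance_is_euclidean(self):
        x = np.array([[3.0, 4.0]])
        assert mahalanobis_distances(x, np.zeros(2), np.eye(2))[0] == pytest.approx(5.0)

    def test_diagonal_scaling(self):
        d = mahalanobis_distances(np.array([[0.0, 2.0]]), np.zeros(2),
                                  np.diag([1.0, 4.0]))
        assert d[0] == pytest.approx(1.0)

    def test_singular_matrix_names_collinear_variables(self):
        sigma = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="near-collinear"):
            mahalanobis_distances(np.zeros((1, 2)), np.zeros(2), sigma)


class TestCStep:
    def test_fixed_point_is_returned_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        h = compute_h(30, 3, 0.7)
        subset = c_step(X, np.arange(h), h)
        for _ in range(40):
            nxt = c_step(X, subset, h)
            if np.array_equal(nxt, subset):
                break
            subset = nxt
        assert np.array_equal(c_step(X, subset, h), subset)

    def test_one_dimensional_selects_closest_values(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 5.0, 6.0])[:, None]
        new = c_step(x, np.array([0, 1, 2, 3]), 4)
        assert np.array_equal(new, [0, 1, 2, 3])

    def test_determinant_never_increases(self):
        # concentration property across many random instances
        rng = np.random.default_rng(42)
        violations = 0
        for _ in range(300):
            n = int(rng.integers(15, 40))
            p = int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            h = compute_h(n, p, float(rng.uniform(0.5, 1.0)))
            start = np.sort(rng.choice(n, h, replace=False))

            def ml_det(idx):
                sub = X[idx]
                c = sub - sub.mean(axis=0)
                return np.linalg.det(c.T @ c / len(idx))

            try:
                new = c_step(X, start, h)
            except DegenerateSubsetError:
                continue
            if ml_det(new) > ml_det(start) + 1e-10:
                violations += 1
        assert violations == 0

    def test_degenerate_subset_signals_redraw(self):
        X = np.zeros((10, 2))
        X[:, 0] = np.arange(10.0)  # second column constant => singular
        with pytest.raises(DegenerateSubsetError):
            c_step(X, np.arange(4), 5)


class TestFastMCD:
    def test_matches_exhaustive_search(self):
        h = compute_h(12, 2, 0.5)
        for seed in range(5):
            X = np.random.default_rng(seed).standard_normal((12, 2))
            est = fast_mcd(X, alpha=0.5, seed=seed)
            assert est.determinant == pytest.approx(brute_force_min_det(X, h),
                                                    abs=1e-8)

    def test_alpha_one_equals_classical_moments(self):
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal([0, 0, 0], np.eye(3), size=80)
        est = fast_mcd(X, alpha=1.0, seed=0)
        assert est.c0 == 1.0
        assert np.allclose(est.location, X.mean(axis=0))
        assert np.allclose(est.scatter, np.cov(X.T, bias=True))

    def test_same_seed_is_bit_identical(self):
        X = np.random.default_rng(2).standard_normal((40, 3))
        a = fast_mcd(X, alpha=0.75, seed=123)
        b = fast_mcd(X, alpha=0.75, seed=123)
        assert np.array_equal(a.subset_indices, b.subset_indices)
        assert np.array_equal(a.scatter, b.scatter)

    def test_rank_deficient_data_errors(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((30, 1))
        X = np.column_stack([base, 2 * base])  # exactly collinear
        with pytest.raises((ValueError, DegenerateSubsetError),
                           match="rank-deficient|singular"):
            fast_mcd(X, alpha=0.75, seed=0)

    def test_agrees_with_sklearn_location(self):
        # independent robust-covariance implementation as a cross-check: both
        # should identify the same clean bulk against planted contamination
        from sklearn.covariance import MinCovDet

        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 3))
        X[:6] += 12.0  # gross cluster
        est = fast_mcd(X, alpha=0.5, seed=0)
        skl = MinCovDet(support_fraction=0.5, random_state=0).fit(X)
        assert np.allclose(est.location, skl.location_, atol=0.35)
        assert not np.any(est.subset_indices < 6)


class TestConsistencyFactor:
    def test_no_trimming(self):
        assert consistency_factor(100, 5, 100) == 1.0

    def test_trimming_inflates(self):
        assert consistency_factor(100, 5, 70) > 1.0

    def test_univariate_half_sample_matches_quadrature(self):
        # oracle: variance of the central half of a standard normal by
        # numerical integration; c0 is its reciprocal
        n, h = 1000, 500
        q = h / n
        z_star = stats.norm.ppf((1 + q) / 2)
        trunc_var, _ = integrate.quad(
            lambda z: z**2 * stats.norm.pdf(z), -z_star, z_star)
        oracle = q / trunc_var
        assert consistency_factor(n, 1, h) == pytest.approx(oracle, abs=1e-6)


class TestOutlyingness:
    @pytest.mark.parametrize("m,r", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.75)])
    def test_reference_points(self, m, r):
        assert outlyingness(np.array([m]))[0] == pytest.approx(r)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            outlyingness(np.array([-0.1]))

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_monotone_into_unit_interval(self, ms):
        m = np.sort(np.unique(np.asarray(ms)))
        m = m[np.concatenate([[True], np.diff(m) > 1e-9])]  # resolvable gaps
        r = outlyingness(m)
        assert np.all((r >= 0) & (r < 1))
        assert len(m) < 2 or np.all(np.diff(r) > 0)


class TestSimulateThreshold:
    def _est_1d(self):
        from cohortqc.mcd import RobustLocationScatter
        return RobustLocationScatter(np.zeros(1), np.eye(1), 10, 1.0, 1.0,
                                     np.arange(10), 1.0)

    def test_eps_one_is_pooled_maximum(self):
        est = self._est_1d()
        thr = simulate_threshold(est, 50, 1.0, n_sims=10,
                                 seed=np.random.default_rng(0))
        # recompute the pooled max with the same stream
        z = np.random.default_rng(0).standard_normal((500, 1))
        r = outlyingness(np.abs(z[:, 0]))
        assert thr == pytest.approx(r.max())

    def test_univariate_closed_form(self):
        # pooled 0.99 percentile of r(|Z|) is 1 - 1/(1 + Phi^-1(0.995))
        est = self._est_1d()
        thr = simulate_threshold(est, 1000, 0.99, n_sims=100, seed=7)
        oracle = 1 - 1 / (1 + stats.norm.ppf(0.995))
        assert thr == pytest.approx(oracle, abs=0.01)

    def test_flags_invariant_under_joint_rescaling(self):
        rng = np.random.default_rng(5)
        X = standardized(rng.standard_normal((80, 3)))
        flags_a = detect_mcd(make_prepared(X), seed=9).flags
        flags_b = detect_mcd(make_prepared(3.0 * X + 5.0), seed=9).flags
        assert np.array_equal(flags_a, flags_b)


class TestCorrMax:
    def test_identity_covariance_returns_deviations(self):
        from cohortqc.mcd import RobustLocationScatter
        est = RobustLocationScatter(np.zeros(2), np.eye(2), 5, 1.0, 1.0,
                                    np.arange(5), 1.0)
        w = corr_max_contributions(np.array([[3.0, 4.0]]), est)
        assert np.allclose(w, [[3.0, 4.0]])
        assert np.sum(w**2) == pytest.approx(25.0)

    def test_conservation_identity_random_draws(self):
        # sum_j w_ij^2 == m_i^2 for random PD covariances
        rng = np.random.default_rng(11)
        from cohortqc.mcd import RobustLocationScatter
        worst = 0.0
        for _ in range(300):
            p = int(rng.integers(2, 6))
            a = rng.standard_normal((p, p))
            sigma = a @ a.T + 0.5 * np.eye(p)
            mu = rng.standard_normal(p)
            est = RobustLocationScatter(mu, sigma, p + 1, 1.0, 1.0,
                                        np.arange(p + 1), 1.0)
            x = rng.standard_normal((4, p))
            w = corr_max_contributions(x, est)
            m = mahalanobis_distances(x, mu, sigma)
            worst = max(worst, np.abs((w**2).sum(axis=1) - m**2).max())
        assert worst < 1e-8


class TestDetectMCD:
    def test_gross_outlier_flagged_with_top_contribution(self):
        rng = np.random.default_rng(21)
        X = standardized(rng.standard_normal((100, 5)))
        X[7, 2] = 20.0
        res = detect_mcd(make_prepared(X), seed=3)
        assert res.flags[7]
        assert res.ranked_contributions(7, top=1)[0][0] == "v2"

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(22)
        X = standardized(rng.standard_normal((60, 4)))
        prep = make_prepared(X)
        prep.values[:, 1] = 0.0
        prep.constant_columns = ["v1"]
        with pytest.warns(UserWarning, match="constant"):
            res = detect_mcd(prep, seed=0)
        assert res.dropped_variables == ["v1"]
        assert res.contributions.shape == (60, 3)

    def test_reproducible_from_seed(self, small_variants):
        prep = small_variants["unadjusted"]
        a = detect_mcd(prep, seed=17)
        b = detect_mcd(prep, seed=17)
        assert np.array_equal(a.flags, b.flags)
        assert a.threshold == b.threshold
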