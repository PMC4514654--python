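"""Stage primitives and the stagewise / TLS solvers."""

import numpy as np
import pytest
from scipy import linalg, stats

from sparsegrn.solvers import (
    DegenerateInputError,
    SolverOptions,
    estimate_nonnull_params,
    estimate_null_sigma,
    fac_threshold,
    matched_filter,
    refine_support,
    smomp_solve,
    stomp_solve,
    tls_solve,
    tpr_beta,
)

from conftest import make_sparse_system


class TestMatchedFilter:
    def test_zero_residual_gives_zero(self, rng):
        Phi = rng.normal(size=(6, 9))
        assert np.all(matched_filter(Phi, np.zeros(6)) == 0)

    def test_orthonormal_identity(self, rng):
        Q = linalg.qr(rng.normal(size=(8, 8)))[0]
        x = rng.normal(size=8)
        np.testing.assert_allclose(matched_filter(Q, Q @ x), x, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        Phi = rng.normal(size=(8, 12))
        r = rng.normal(size=8)
        oracle = np.array(
            [sum(Phi[i, j] * r[i] for i in range(8)) for j in range(12)]
        )
        np.testing.assert_allclose(matched_filter(Phi, r), oracle, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            matched_filter(rng.normal(size=(8, 12)), rng.normal(size=7))


class TestNullSigma:
    def test_recovers_known_sigma_from_pure_gaussian(self, rng):
        c = rng.normal(0, 1, size=100_000)
        sigma, iters = estimate_null_sigma(c, t=2.5, variance_tol=1e-3)
        assert abs(sigma - 1.0) < 0.05
        assert iters >= 1

    def test_outlier_deletion_beats_naive_estimate(self, rng):
        c = np.r_[rng.normal(0, 1, size=10_000), np.full(50, 100.0)]
        naive = np.sqrt(np.mean(c**2))
        sigma, _ = estimate_null_sigma(c, t=2.5, variance_tol=1e-3)
        assert naive > 5
        assert abs(sigma - 1.0) < 0.10

    def test_all_zero_flags_degenerate(self):
        sigma, _ = estimate_null_sigma(np.zeros(10), t=2.5)
        assert sigma == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(DegenerateInputError):
            estimate_null_sigma(np.array([]), t=2.5)


class TestFacThreshold:
    def test_alpha0_override_clamps_to_range_floor(self):
        # alpha0 = 0.3 -> 0.85 quantile ~ 1.036, clamped up to 2.0
        assert fac_threshold(80, 99, alpha0_override=0.3) == 2.0

    def test_interior_quantile_returned_unchanged(self):
        alpha0 = 2 * stats.norm.sf(2.5)  # makes the raw quantile exactly 2.5
        t = fac_threshold(80, 99, alpha0_override=alpha0)
        assert abs(t - 2.5) < 1e-12

    def test_formula_matches_brute_force(self):
        m, n, k, S = 1000, 99, 5, 10
        alpha0 = (m - k) / (S * (n - k))
        with pytest.raises(ValueError):
            # alpha0 > 1 here: formula demands an error, not a silent clamp
            fac_threshold(m, n, k_hint=k, S=S)
        m = 100
        alpha0 = (m - k) / (S * (n - k))
        expected = np.clip(stats.norm.ppf(1 - alpha0 / 2), 2.0, 3.0)
        assert abs(fac_threshold(m, n, k_hint=k, S=S) - expected) < 1e-12

    def test_invalid_k_hint(self):
        with pytest.raises(ValueError):
            fac_threshold(10, 5, k_hint=7)


class TestNonnullFit:
    def test_single_coefficient(self):
        mu, s2 = estimate_nonnull_params(np.array([-4.0]))
        assert mu == 4.0 and s2 > 0 and s2 < 1e-6

    def test_symmetric_pair_folds(self):
        mu, s2 = estimate_nonnull_params(np.array([3.0, -3.0]))
        assert mu == 3.0 and s2 < 1e-6

    def test_folded_normal_parameter_recovery(self, rng):
        c = np.abs(rng.normal(5.0, 1.0, size=100_000))
        mu, s2 = estimate_nonnull_params(c)
        assert abs(mu - 5.0) / 5.0 < 0.02
        assert abs(s2 - 1.0) < 0.05

    def test_empty_raises(self):
        with pytest.raises(DegenerateInputError):
            estimate_nonnull_params(np.array([]))


class TestTprBeta:
    def test_far_separated_signal_saturates(self):
        assert tpr_beta(mu_s=12.0, sigma2_s=1.0, t_s=2.0, sigma1_s=1.0) > 1 - 1e-6

    def test_null_centred_case_closed_form(self):
        beta = tpr_beta(mu_s=0.0, sigma2_s=1.0, t_s=2.0, sigma1_s=1.0)
        assert abs(beta - 2 * stats.norm.sf(2.0)) < 1e-12

    def test_matches_monte_carlo(self, rng):
        for _ in range(5):
            mu = rng.uniform(0, 5)
            s2 = rng.uniform(0.5, 2)
            t, s1 = rng.uniform(2, 3), rng.uniform(0.5, 2)
            beta = tpr_beta(mu, s2, t, s1)
            draws = np.abs(rng.normal(mu, s2, size=1_000_000))
            hat = np.mean(draws > t * s1)
            se = max(np.sqrt(hat * (1 - hat) / draws.size), 1e-6)
            assert abs(beta - hat) < 3 * se + 1e-4

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            tpr_beta(1.0, 0.0, 2.0, 1.0)


class TestRefineSupport:
    def test_beta_one_keeps_all(self, rng):
        cand = np.array([4, 7, 9])
        kept = refine_support(rng.normal(size=3), cand, beta=1.0)
        np.testing.assert_array_equal(kept, cand)

    def test_floor_to_zero_raised_to_min_keep(self):
        kept = refine_support(np.array([0.1, -5.0, 2.0]),
                              np.array([2, 5, 8]), beta=0.2)
        np.testing.assert_array_equal(kept, [5])  # largest magnitude only

    def test_matches_sorting_oracle(self, rng):
        x = rng.normal(size=20)
        cand = np.arange(100, 120)
        kept = refine_support(x, cand, beta=0.5)
        oracle = cand[np.argsort(-np.abs(x), kind="stable")[:10]]
        np.testing.assert_array_equal(kept, np.sort(oracle))

    def test_tie_breaks_to_lower_index(self):
        kept = refine_support(np.array([1.0, 1.0, 1.0]),
                              np.array([3, 1, 2]), beta=0.4)
        np.testing.assert_array_equal(kept, [1])


@pytest.mark.parametrize("solve", [smomp_solve, stomp_solve],
                         ids=["smomp", "stomp"])
class TestStagewiseSolvers:
    def test_zero_observation(self, solve, rng):
        Phi = rng.normal(size=(8, 16))
        sol = solve(Phi, np.zeros(8))
        assert sol.support.size == 0
        assert np.all(sol.coefficients == 0)
        assert sol.converged_reason == "empty_candidate"

    def test_exact_recovery_noise_free(self, solve, rng):
        for _ in range(20):
            Phi, x, y = make_sparse_system(rng, n=64, m=32, k=3)
            sol = solve(Phi, y)
            err = np.linalg.norm(sol.coefficients - x) / np.linalg.norm(x)
            assert err < 1e-6

    def test_support_monotone_and_residual_orthogonal(self, solve, rng):
        # support only grows; after each projection the residual is
        # orthogonal to the selected columns
        Phi, x, y = make_sparse_system(rng, n=40, m=25, k=4)
        y = y + rng.normal(0, 0.05, size=25)
        sol = solve(Phi, y)
        Phi_n = Phi / np.linalg.norm(Phi, axis=0)
        seen = set()
        for t in sol.trace:
            assert set(t.kept_set) <= set(range(40))
            assert len(t.kept_set) <= t.candidate_set_size
            assert 0 < t.tpr_beta <= 1
            assert np.isfinite(
                [t.null_sigma, t.nonnull_mean, t.nonnull_sigma, t.threshold,
                 t.tpr_beta, t.residual_norm]
            ).all()
            seen |= set(t.kept_set)
        assert set(sol.support) == seen
        r = y - Phi_n @ np.where(
            np.isin(np.arange(40), sol.support),
            sol.coefficients * np.linalg.norm(Phi, axis=0), 0.0,
        )
        assert np.max(np.abs(Phi_n[:, sol.support].T @ r)) < 1e-8

    def test_residual_norms_non_increasing(self, solve, rng):
        for _ in range(100):
            Phi, x, y = make_sparse_system(rng, n=30, m=20, k=3)
            y = y + rng.normal(0, 0.1, size=20)
            sol = solve(Phi, y)
            norms = [t.residual_norm for t in sol.trace]
            assert all(b <= a + 1e-10 for a, b in zip(norms, norms[1:]))

    def test_zero_column_rejected(self, solve, rng):
        Phi = rng.normal(size=(6, 4))
        Phi[:, 2] = 0.0
        with pytest.raises(ValueError):
            solve(Phi, rng.normal(size=6))

    def test_coefficients_reported_on_original_column_scale(self, solve, rng):
        Phi, x, y = make_sparse_system(rng, n=32, m=24, k=2)
        scaled = Phi * rng.uniform(0.5, 3.0, size=32)
        sol = solve(scaled, y)
        np.testing.assert_allclose(scaled @ sol.coefficients, y, atol=1e-6)


class TestSolverOptions:
    def test_from_mapping_roundtrip(self):
        opts = SolverOptions.from_mapping(
            {"max_stages": 5, "alpha0": 0.3, "min_keep": 2}
        )
        assert opts.max_stages == 5 and opts.alpha0 == 0.3

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            SolverOptions.from_mapping({"stages": 5})

    @pytest.mark.parametrize(
        "kwargs", [dict(max_stages=0), dict(residual_tol=0.0),
                   dict(alpha0=1.5), dict(min_keep=0)],
    )
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverOptions(**kwargs)


class TestTotalLeastSquares:
    def test_consistent_noise_free_limit(self, rng):
        Phi = rng.normal(size=(30, 5))
        x = rng.normal(size=5)
        xhat = tls_solve(Phi, Phi @ x)
        np.testing.assert_allclose(xhat, x, atol=1e-8)

    def test_matches_svd_oracle(self, rng):
        Phi = rng.normal(size=(50, 5))
        b = Phi @ rng.normal(size=5) + rng.normal(0, 0.3, size=50)
        # oracle: full SVD of the augmented matrix via eigendecomposition
        M = np.column_stack([Phi, b])
        w, V = np.linalg.eigh(M.T @ M)
        v = V[:, 0]
        oracle = -v[:-1] / v[-1]
        np.testing.assert_allclose(tls_solve(Phi, b), oracle, atol=1e-10)

    def test_eckart_young_null_direction(self, rng):
        # [x; -1] attains the minimal Rayleigh quotient of [Phi b]^T [Phi b]
        Phi = rng.normal(size=(20, 3))
        b = Phi @ rng.normal(size=3) + rng.normal(0, 0.2, size=20)
        x = tls_solve(Phi, b)
        M = np.column_stack([Phi, b])
        v = np.r_[x, -1.0]
        rq = v @ (M.T @ M) @ v / (v @ v)
        smin2 = linalg.svdvals(M)[-1] ** 2
        assert abs(rq - smin2) < 1e-8 * max(1.0, smin2)

    def test_non_generic_failure_raises(self):
        Phi = np.array([[1.0], [0.0]])
        b = np.array([0.0, 2.0])
        with pytest.raises(linalg.LinAlgError):
            tls_solve(Phi, b)
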