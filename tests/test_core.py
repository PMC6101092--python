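"""Estimator unit tests: standardization, ALS updates, IRLS fit, prediction.

Expected values for the closed-form updates and the full fit come from
independent numerical optimizers (scipy) run on the same objectives.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from hiscom.containers import DataError, Hierarchy, PeptideMatrix, Phenotype
from hiscom.core import (
    FitError,
    ModelConfig,
    beta_update,
    compute_component_scores,
    fit_hiscom_arrays,
    irls_als_fit,
    penalized_objective,
    predict_proba,
    standardize_apply,
    standardize_fit,
    weight_update,
    _expit,
)

from conftest import make_cohort


def _std(values):
    return (values - values.mean(0)) / values.std(0, ddof=1)


class TestStandardizer:
    def test_sample_sd_convention(self):
        X = PeptideMatrix(["a", "b", "c"], ["p"], [[1.0], [2.0], [3.0]])
        std = standardize_fit(X)
        out = standardize_apply(std, X)
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(20)
        v = (v - v.mean()) / v.std(ddof=1)
        X = PeptideMatrix([f"s{i}" for i in range(20)], ["p"], v[:, None])
        out = standardize_apply(standardize_fit(X), X)
        np.testing.assert_allclose(out[:, 0], v, atol=1e-12)

    def test_constant_column_rejected(self):
        X = PeptideMatrix(["a", "b", "c"], ["pep7"], [[5.0], [5.0], [5.0]])
        with pytest.raises(DataError, match="pep7"):
            standardize_fit(X)

    def test_apply_uses_training_statistics(self):
        Xtr = PeptideMatrix(["a", "b", "c"], ["p"], [[1.0], [2.0], [3.0]])
        std = standardize_fit(Xtr)
        Xnew = PeptideMatrix(["d"], ["p"], [[4.0]])
        np.testing.assert_allclose(standardize_apply(std, Xnew), [[2.0]])


class TestComponentScores:
    def test_zero_weights_and_single_peptide_identity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 3))
        groups = [np.array([0]), np.array([1, 2])]
        assert np.all(compute_component_scores(X, groups, np.zeros(3)) == 0)
        F = compute_component_scores(X, groups, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(F[:, 0], X[:, 0])

    def test_panel_scale_column_count(self):
        rng = np.random.default_rng(2)
        sizes = [2] * 107 + [1] * 17  # 231 peptides over 124 proteins
        X = rng.standard_normal((5, 231))
        groups, start = [], 0
        for t in sizes:
            groups.append(np.arange(start, start + t))
            start += t
        F = compute_component_scores(X, groups, rng.standard_normal(231))
        assert F.shape == (5, 124)


class TestBetaUpdate:
    def test_infinite_shrinkage(self):
        rng = np.random.default_rng(3)
        F = np.column_stack([np.ones(10), rng.standard_normal((10, 2))])
        z = rng.standard_normal(10)
        v = np.full(10, 0.25)
        mask = np.array([False, True, True])
        beta = beta_update(F, z, v, 1e12, mask)
        assert np.all(np.abs(beta[1:]) < 1e-6)
        assert abs(beta[0]) > 0  # unpenalized intercept survives

    def test_orthonormal_projection(self):
        q, _ = np.linalg.qr(np.random.default_rng(4).standard_normal((8, 3)))
        z = np.random.default_rng(5).standard_normal(8)
        beta = beta_update(q, z, np.ones(8), 0.0, np.zeros(3, dtype=bool))
        np.testing.assert_allclose(beta, q.T @ z, atol=1e-10)

    def test_matches_numerical_quadratic_minimizer(self):
        F = np.array([[1.0, 0.5, -0.2], [1.0, -1.0, 0.3], [1.0, 0.1, 1.5]])
        z = np.array([0.7, -0.3, 1.1])
        v = np.array([0.2, 0.25, 0.15])
        mask = np.array([True, True, True])
        lam = 3.0

        def objective(b):
            r = z - F @ b
            return v @ r**2 + lam * (b @ b)

        res = minimize(objective, np.zeros(3), method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12, maxiter=10000))
        np.testing.assert_allclose(beta_update(F, z, v, lam, mask), res.x, atol=1e-6)

    def test_singular_unpenalized_system_raises(self):
        F = np.ones((4, 2))  # duplicated columns, no ridge
        with pytest.raises(FitError, match="lambda_prot"):
            beta_update(F, np.ones(4), np.ones(4), 0.0, np.zeros(2, dtype=bool))


class TestWeightUpdate:
    def test_zero_paths_give_zero_weights(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 4))
        pep_protein = np.array([0, 0, 1, 1])
        w = weight_update(X, pep_protein, rng.standard_normal(10), np.full(10, 0.2),
                          np.zeros(2), np.zeros(10), lambda_pep=5.0)
        np.testing.assert_allclose(w, 0.0, atol=1e-12)

    def test_duplicate_peptides_get_equal_weights(self):
        rng = np.random.default_rng(7)
        col = rng.standard_normal(12)
        X = np.column_stack([col, col, rng.standard_normal(12)])
        pep_protein = np.array([0, 0, 1])
        w = weight_update(X, pep_protein, rng.standard_normal(12), np.full(12, 0.25),
                          np.array([0.8, 0.3]), np.zeros(12), lambda_pep=2.0)
        assert abs(w[0] - w[1]) < 1e-10

    def test_unidentifiable_without_penalty(self):
        X = np.random.default_rng(8).standard_normal((5, 2))
        with pytest.raises(FitError, match="unidentifiable"):
            weight_update(X, np.array([0, 1]), np.zeros(5), np.ones(5),
                          np.array([1.0, 0.0]), np.zeros(5), lambda_pep=0.0)

    def test_matches_numerical_minimizer(self):
        rng = np.random.default_rng(9)
        n, X = 12, rng.standard_normal((12, 4))
        pep_protein = np.array([0, 0, 1, 1])
        z, v = rng.standard_normal(n), np.full(n, 0.21)
        beta_k = np.array([0.9, -0.4])
        offset = rng.standard_normal(n) * 0.1
        lam = 4.0

        def objective(w):
            eta = offset + (X * beta_k[pep_protein]) @ w
            return v @ (z - eta) ** 2 + lam * (w @ w)

        res = minimize(objective, np.zeros(4), method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000))
        got = weight_update(X, pep_protein, z, v, beta_k, offset, lam)
        np.testing.assert_allclose(got, res.x, atol=1e-6)


class TestPenalizedObjective:
    def test_reduces_to_loglik_without_penalty(self):
        rng = np.random.default_rng(10)
        X = _std(rng.standard_normal((15, 3)))
        groups = [np.array([0, 1]), np.array([2])]
        w = rng.standard_normal(3)
        beta = rng.standard_normal(3)
        y = rng.integers(0, 2, 15).astype(float)
        cfg = ModelConfig(lambda_pep=0.0, lambda_prot=0.0)
        eta = beta[0] + compute_component_scores(X, groups, w) @ beta[1:]
        mu = _expit(eta)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        assert penalized_objective(X, y, groups, w, beta, cfg) == pytest.approx(ll, abs=1e-10)

    def test_penalty_difference_identity(self):
        """phi1(w) - phi1(w') with identical eta differs only by the w-ridge."""
        rng = np.random.default_rng(11)
        X = _std(rng.standard_normal((10, 2)))
        groups = [np.array([0, 1])]
        y = rng.integers(0, 2, 10).astype(float)
        cfg = ModelConfig(lambda_pep=7.0, lambda_prot=3.0)
        w1, w2 = np.array([0.5, -0.2]), np.array([1.4, 0.3])
        beta = np.array([0.1, 0.8])
        d = penalized_objective(X, y, groups, w1, beta, cfg) - penalized_objective(
            X, y, groups, w2, beta, cfg
        )
        eta1 = beta[0] + compute_component_scores(X, groups, w1) @ beta[1:]
        eta2 = beta[0] + compute_component_scores(X, groups, w2) @ beta[1:]
        ll = lambda eta: float(y @ np.log(_expit(eta)) + (1 - y) @ np.log(1 - _expit(eta)))
        expected = (ll(eta1) - ll(eta2)) - 0.5 * 7.0 * (w1 @ w1 - w2 @ w2)
        assert d == pytest.approx(expected, abs=1e-10)

    def test_fixed_instance_hand_computation(self):
        # 2 samples, 1 protein, 1 peptide: every term written out by hand
        X = np.array([[1.0], [-1.0]])
        groups = [np.array([0])]
        w = np.array([0.5])
        beta = np.array([0.2, 0.4])  # intercept, path
        y = np.array([1.0, 0.0])
        cfg = ModelConfig(lambda_pep=10.0, lambda_prot=10.0, penalize_intercept=True)
        eta = np.array([0.2 + 0.4 * 0.5, 0.2 - 0.4 * 0.5])
        ll = np.log(1 / (1 + np.exp(-eta[0]))) + np.log(1 - 1 / (1 + np.exp(-eta[1])))
        expected = ll - 0.5 * 10 * 0.25 - 0.5 * 10 * (0.04 + 0.16)
        got = penalized_objective(X, y, groups, w, beta, cfg)
        assert got == pytest.approx(expected, abs=1e-12)


def _oracle_phi1(Xstd, y, groups, cfg, covariates=None, n_starts=8, scale=0.5):
    """Multistart quasi-Newton maximizer of the penalized log-likelihood."""
    p = Xstd.shape[1]
    K = len(groups)
    n_cov = 0 if covariates is None else covariates.shape[1]

    def neg(theta):
        w, beta = theta[:p], theta[p : p + K + 1]
        bcov = theta[p + K + 1 :] if n_cov else None
        return -penalized_objective(
            Xstd, y, groups, w, beta, cfg, covariates=covariates, beta_cov=bcov
        )

    best = np.inf
    for s in range(n_starts):
        x0 = np.random.default_rng(s).standard_normal(p + K + 1 + n_cov) * scale
        res = minimize(neg, x0, method="L-BFGS-B", options=dict(maxiter=2000))
        best = min(best, res.fun)
    return -best


class TestIrlsAlsFit:
    def test_matches_brute_force_maximizer(self):
        """Converged objective agrees with a generic numerical optimizer."""
        for seed in range(3):
            X, hier, ph = make_cohort(n=40, seed=seed)
            cfg = ModelConfig()
            Xstd = _std(X.values)
            _, groups = hier.groups_for(X.peptide_ids)
            y = ph.response.astype(float)
            w, beta, _, trace, conv, _, _ = fit_hiscom_arrays(Xstd, y, groups, cfg)
            oracle = _oracle_phi1(Xstd, y, groups, cfg)
            assert abs(trace[-1] - oracle) / abs(oracle) < 1e-5

    def test_intercept_only_limit(self, small_cohort):
        X, hier, ph = small_cohort
        cfg = ModelConfig(
            lambda_pep=1e8, lambda_prot=1e8,
            penalize_intercept=False, penalize_covariates=True,
        )
        fit = irls_als_fit(X, ph, hier, cfg)
        pi = predict_proba(fit, X, ph)
        np.testing.assert_allclose(pi, ph.response.mean(), atol=1e-3)

    def test_representation_invariance(self, small_cohort):
        """Permuting peptide columns and protein order leaves predictions unchanged."""
        X, hier, ph = small_cohort
        cfg = ModelConfig()
        fit = irls_als_fit(X, ph, hier, cfg)
        pi = predict_proba(fit, X, ph)

        rng = np.random.default_rng(42)
        perm = rng.permutation(X.n_peptides)
        Xp = X.subset_peptides([X.peptide_ids[i] for i in perm])
        pairs = [(p, hier.mapping[p]) for p in reversed(Xp.peptide_ids)]
        hier_p = Hierarchy.from_pairs(pairs)  # reversed protein first-appearance order
        fit_p = irls_als_fit(Xp, ph, hier_p, cfg)
        pi_p = predict_proba(fit_p, Xp, ph)
        np.testing.assert_allclose(pi_p, pi, atol=1e-10)

    def test_random_initializations_reach_same_solution(self):
        """Dual penalties make the (w, beta) split identifiable.

        Uses a cohort with strong enough association that the solution keeps
        both components active (a collapsed component is exactly zero in the
        limit but refits approach it at different rates, which would make the
        coefficient comparison vacuous).
        """
        X, hier, ph = make_cohort(n=120, seed=1, signal=2.0)
        cfg = ModelConfig(tol=1e-12, max_outer_iter=2000)
        Xstd = _std(X.values)
        _, groups = hier.groups_for(X.peptide_ids)
        y = ph.response.astype(float)
        cov = ph.covariate_matrix()
        objectives, solutions = [], []
        rng = np.random.default_rng(0)
        for _ in range(10):
            w0 = rng.standard_normal(X.n_peptides) * 0.5
            b0 = rng.standard_normal(1 + hier.n_proteins + 2) * 0.5
            w, beta, bcov, trace, conv, _, _ = fit_hiscom_arrays(
                Xstd, y, groups, cfg, covariates=cov, w0=w0, beta0=b0
            )
            # sign convention for comparability
            for k, idx in enumerate(groups):
                if w[idx].sum() < 0:
                    w[idx] *= -1
                    beta[k + 1] *= -1
            objectives.append(trace[-1])
            solutions.append(np.concatenate([w, beta, bcov]))
        objectives = np.asarray(objectives)
        assert np.ptp(objectives) / abs(objectives.mean()) < 1e-6
        ref = solutions[0]
        for sol in solutions[1:]:
            np.testing.assert_allclose(sol, ref, atol=1e-4)

    def test_single_peptide_proteins_match_product_parameterization(self):
        """With T_k = 1 the fit is governed by theta_k = w_k * beta_k with an
        induced sqrt(lambda_pep * lambda_prot) * |theta_k| penalty."""
        rng = np.random.default_rng(12)
        n, K = 50, 2
        Xstd = _std(rng.standard_normal((n, K)))
        eta = 1.5 * Xstd[:, 0]
        y = (rng.random(n) < _expit(eta)).astype(float)
        cfg = ModelConfig(lambda_pep=2.0, lambda_prot=3.0, penalize_intercept=False)
        groups = [np.array([0]), np.array([1])]
        w, beta, _, trace, _, _, _ = fit_hiscom_arrays(Xstd, y, groups, cfg)
        products = w * beta[1:]

        lam_eq = np.sqrt(cfg.lambda_pep * cfg.lambda_prot)

        def neg(theta):
            eta = theta[0] + Xstd @ theta[1:]
            mu = np.clip(_expit(eta), 1e-10, 1 - 1e-10)
            ll = y @ np.log(mu) + (1 - y) @ np.log(1 - mu)
            return -(ll - lam_eq * np.sum(np.sqrt(theta[1:] ** 2 + 1e-14)))

        best, bx = np.inf, None
        for s in range(6):
            res = minimize(neg, np.random.default_rng(s).standard_normal(3) * 0.3,
                           method="Nelder-Mead",
                           options=dict(xatol=1e-9, fatol=1e-11, maxiter=20000))
            if res.fun < best:
                best, bx = res.fun, res.x
        np.testing.assert_allclose(products, bx[1:], atol=1e-4)

    def test_inner_updates_never_increase_working_objective(self):
        for seed in range(5):
            X, hier, ph = make_cohort(n=30, seed=seed)
            Xstd = _std(X.values)
            _, groups = hier.groups_for(X.peptide_ids)
            _, _, _, _, _, _, inner = fit_hiscom_arrays(
                Xstd, ph.response.astype(float), groups, ModelConfig(), track_inner=True
            )
            for sweep in inner:
                diffs = np.diff(np.asarray(sweep))
                assert np.all(diffs <= 1e-8 * np.abs(np.asarray(sweep[:-1])) + 1e-10)

    def test_objective_trace_is_monotone(self, small_cohort):
        X, hier, ph = small_cohort
        fit = irls_als_fit(X, ph, hier, ModelConfig())
        trace = np.asarray(fit.objective_trace)
        assert np.all(np.diff(trace) >= -1e-9 * (np.abs(trace[:-1]) + 1.0))

    def test_requires_two_samples_per_class(self, small_cohort):
        X, hier, ph = small_cohort
        y = np.zeros(X.n_samples, dtype=int)
        y[0] = 1
        bad = Phenotype(X.sample_ids, y, ph.age, ph.sex)
        with pytest.raises(DataError, match="response class"):
            irls_als_fit(X, bad, hier, ModelConfig())

    def test_sign_convention(self, small_cohort):
        X, hier, ph = small_cohort
        fit = irls_als_fit(X, ph, hier, ModelConfig())
        for idx in fit.groups():
            assert fit.w[idx].sum() >= 0


class TestPredict:
    def test_zero_coefficients_give_half(self, small_cohort):
        X, hier, ph = small_cohort
        fit = irls_als_fit(X, ph, hier, ModelConfig())
        from dataclasses import replace
        zero = replace(
            fit,
            w=np.zeros_like(fit.w),
            beta=np.zeros_like(fit.beta),
            beta_age=0.0,
            beta_sex=0.0,
        )
        np.testing.assert_allclose(predict_proba(zero, X, ph), 0.5)

    def test_direct_evaluation_of_prediction_equation(self):
        """w=(1,-1), beta=(0, 0.5), x=(1,0) -> pi = logistic(0.5)."""
        X = PeptideMatrix(["s1", "s2", "s3"], ["p1", "p2"],
                          [[1.0, 0.0], [0.0, 1.0], [2.0, -1.0]])
        hier = Hierarchy.from_pairs([("p1", "A"), ("p2", "A")])
        from hiscom.core import HisComFit, Standardizer
        ident = Standardizer(("p1", "p2"), np.zeros(2), np.ones(2))
        fit = HisComFit(
            peptide_ids=("p1", "p2"), protein_ids=("A",), pep_protein_ids=("A", "A"),
            w=np.array([1.0, -1.0]), beta=np.array([0.0, 0.5]),
            beta_age=None, beta_sex=None, standardizer=ident,
            config=ModelConfig(), objective_trace=(0.0,), converged=True, n_iter=1,
        )
        pi = predict_proba(fit, X)
        assert pi[0] == pytest.approx(1 / (1 + np.exp(-0.5)), abs=1e-12)
        assert pi[0] == pytest.approx(0.62246, abs=1e-5)

    def test_monotone_in_positive_direction_peptide(self, small_cohort):
        X, hier, ph = small_cohort
        fit = irls_als_fit(X, ph, hier, ModelConfig())
        i = int(np.argmax(np.abs(fit.w)))
        k = fit.protein_ids.index(fit.pep_protein_ids[i])
        direction = np.sign(fit.w[i] * fit.beta[k + 1])
        if direction == 0:
            pytest.skip("degenerate direction")
        bumped = X.values.copy()
        bumped[:, i] += direction * 0.5
        X2 = PeptideMatrix(X.sample_ids, X.peptide_ids, bumped)
        assert np.all(predict_proba(fit, X2, ph) > predict_proba(fit, X, ph))

    def test_unknown_columns_rejected(self, small_cohort):
        X, hier, ph = small_cohort
        fit = irls_als_fit(X, ph, hier, ModelConfig())
        Xbad = PeptideMatrix(X.sample_ids, ["zzz"] + list(X.peptide_ids[1:]), X.values)
        with pytest.raises(DataError):
            predict_proba(fit, Xbad, ph)
        with pytest.raises(DataError, match="covariates"):
            predict_proba(fit, X, None)
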