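"""Hierarchical structural component model (HisCoM) for binary outcomes.

The model collapses peptide columns into one latent component per protein,

    f_jk = sum_i x_jki * w_ki ,

and regresses the binary drug response on the K component scores plus age and
sex through a logit link,

    logit(pi_j) = beta_0 + sum_k f_jk beta_k + AGE_j beta_age + SEX_j beta_sex .

Peptide weights w and protein path coefficients beta are estimated jointly by
maximizing a doubly ridge-penalized Bernoulli log-likelihood

    phi1 = sum_j log P(y_j; eta_j)
           - (1/2) lambda_pep * ||w||^2
           - (1/2) lambda_prot * sum_{k in mask} beta_k^2 ,

where the beta penalty mask covers the path coefficients (and, following the
printed objective, the intercept by default; covariates are unpenalized by
default).  The maximizer is found by iteratively reweighted least squares
(IRLS): at the current coefficients the working weights v_j = mu_j(1 - mu_j)
and adjusted responses z_j = eta_j + (y_j - mu_j)/v_j define a penalized
weighted least-squares problem

    phi2 = (z - F beta)' V (z - F beta)
           + lambda_pep ||w||^2 + lambda_prot * sum_{k in mask} beta_k^2 ,

which is bilinear in (w, beta) and is solved by alternating least squares
(ALS): each of the two blocks has a closed-form ridge solution, so phi2 is
non-increasing across every update.  The outer loop refreshes (V, z) and
monitors phi1 until its relative change falls below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import DataError, Hierarchy, PeptideMatrix, Phenotype

__all__ = [
    "ModelConfig",
    "Standardizer",
    "HisComFit",
    "standardize_fit",
    "standardize_apply",
    "compute_component_scores",
    "beta_update",
    "weight_update",
    "penalized_objective",
    "irls_als_fit",
    "fit_hiscom_arrays",
    "predict_proba",
]

#: mu is clipped into [MU_EPS, 1 - MU_EPS] so v_j and z_j stay finite under
#: near-separation.
MU_EPS = 1e-10

#: lower bound on the IRLS working weights v_j = mu_j(1 - mu_j).  The floor
#: leaves the gradient term v_j (z_j - eta_j) = y_j - mu_j exact while
#: bounding the working curvature away from zero, so iterations started (or
#: passing) deep in the saturated region of the logistic cannot stall on a
#: flat working problem.  Inactive near any non-separated solution, where
#: v_j is orders of magnitude larger.
V_FLOOR = 1e-4


class FitError(RuntimeError):
    """The estimator could not produce a valid solution."""


@dataclass(frozen=True)
class ModelConfig:
    """Tuning parameters of the HisCoM estimator.

    lambda_pep, lambda_prot
        Ridge parameters for peptide weights and protein path coefficients.
        Both default to 10, the value used throughout the biomarker screen.
    penalize_intercept
        Whether beta_0 enters the protein-level ridge (the printed objective
        sums the beta penalty from k = 0).
    penalize_covariates
        Whether beta_age / beta_sex are penalized; off by default — the
        covariates are estimated freely alongside the penalized peptide terms.
    tol
        Relative-change tolerance on the penalized log-likelihood (outer
        loop) and on the working least-squares objective (inner ALS loop).
    """

    lambda_pep: float = 10.0
    lambda_prot: float = 10.0
    penalize_intercept: bool = True
    penalize_covariates: bool = False
    tol: float = 1e-6
    max_outer_iter: int = 100
    max_inner_iter: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_pep < 0 or self.lambda_prot < 0:
            raise ValueError("ridge parameters must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_outer_iter < 1 or self.max_inner_iter < 1:
            raise ValueError("iteration limits must be positive")


@dataclass(frozen=True)
class Standardizer:
    """Per-peptide location/scale learned on training samples (ddof=1)."""

    peptide_ids: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[1] != len(self.peptide_ids):
            raise DataError(
                f"expected {len(self.peptide_ids)} peptide columns, got {values.shape[1]}"
            )
        return (values - self.mean) / self.sd


def standardize_fit(X: PeptideMatrix) -> Standardizer:
    """Learn per-peptide mean and sample standard deviation (ddof=1).

    Constant columns are rejected: a peptide with zero variance carries no
    contrast and would make the scale undefined.
    """
    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=1) if X.n_samples > 1 else np.zeros(X.n_peptides)
    if np.any(sd <= 0):
        k = int(np.argmax(sd <= 0))
        raise DataError(f"peptide {X.peptide_ids[k]!r} is constant on the training samples")
    return Standardizer(X.peptide_ids, mean, sd)


def standardize_apply(std: Standardizer, X: PeptideMatrix) -> np.ndarray:
    """Apply training statistics to (possibly unseen) samples."""
    if X.peptide_ids != std.peptide_ids:
        raise DataError("peptide columns do not match the standardizer")
    return std.transform(X.values)


def compute_component_scores(
    Xstd: np.ndarray, groups: Sequence[np.ndarray], w: np.ndarray
) -> np.ndarray:
    """Protein component scores f_jk = sum_i x_jki w_ki.

    ``groups`` lists, per protein, the column indices of its peptides; column
    k of the result uses only protein k's peptides.
    """
    Xstd = np.asarray(Xstd, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != (Xstd.shape[1],):
        raise DataError(f"weight vector length {w.shape} does not match {Xstd.shape[1]} peptides")
    F = np.empty((Xstd.shape[0], len(groups)))
    for k, idx in enumerate(groups):
        F[:, k] = Xstd[:, idx] @ w[idx]
    return F


def _groups_to_protein_index(groups: Sequence[np.ndarray], n_peptides: int) -> np.ndarray:
    pep_protein = np.full(n_peptides, -1, dtype=np.intp)
    for k, idx in enumerate(groups):
        pep_protein[idx] = k
    if (pep_protein < 0).any():
        raise DataError("every peptide column must belong to exactly one protein group")
    return pep_protein


def beta_update(
    F_full: np.ndarray,
    z: np.ndarray,
    v: np.ndarray,
    lambda_prot: float,
    penalty_mask: np.ndarray,
) -> np.ndarray:
    """Closed-form ridge solution for the path-coefficient block.

    Minimizes (z - F_full b)' V (z - F_full b) + lambda_prot * sum_mask b^2
    over b via the penalized weighted normal equations.  ``F_full`` holds the
    intercept column, the K component scores and any covariate columns;
    ``penalty_mask`` marks which coefficients carry the ridge.
    """
    F_full = np.asarray(F_full, dtype=float)
    penalty_mask = np.asarray(penalty_mask, dtype=bool)
    G = F_full.T @ (F_full * v[:, None])
    G[np.diag_indices_from(G)] += np.where(penalty_mask, lambda_prot, 0.0)
    rhs = F_full.T @ (v * z)
    try:
        beta = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        raise FitError("unidentifiable; increase lambda_prot") from None
    if not np.all(np.isfinite(beta)):
        raise FitError("unidentifiable; increase lambda_prot")
    return beta


def weight_update(
    Xstd: np.ndarray,
    pep_protein: np.ndarray,
    z: np.ndarray,
    v: np.ndarray,
    beta_k: np.ndarray,
    offset: np.ndarray,
    lambda_pep: float,
) -> np.ndarray:
    """Closed-form ridge solution for the peptide-weight block.

    With beta fixed the fitted logit is offset + sum_i (beta_{k(i)} x_ji) w_i,
    so all weights solve one joint weighted ridge regression of (z - offset)
    on the beta-scaled peptide columns.
    """
    pep_protein = np.asarray(pep_protein, dtype=np.intp)
    scale = np.asarray(beta_k, dtype=float)[pep_protein]
    if lambda_pep == 0 and np.any(scale == 0):
        k = int(pep_protein[np.argmax(scale == 0)])
        raise FitError(f"weights of protein {k} unidentifiable with lambda_pep=0 and beta_k=0")
    C = Xstd * scale
    G = C.T @ (C * v[:, None])
    G[np.diag_indices_from(G)] += lambda_pep
    rhs = C.T @ (v * (z - offset))
    try:
        return np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        raise FitError("weight system singular; increase lambda_pep") from None


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # y*eta - log(1 + e^eta): exact for any eta, unlike clipping mu, which
    # would flatten the objective in the saturated region
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _expit(eta: np.ndarray) -> np.ndarray:
    # scipy.special.expit without the import cost in tight loops
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def penalized_objective(
    Xstd: np.ndarray,
    y: np.ndarray,
    groups: Sequence[np.ndarray],
    w: np.ndarray,
    beta: np.ndarray,
    config: ModelConfig,
    covariates: np.ndarray | None = None,
    beta_cov: np.ndarray | None = None,
) -> float:
    """Penalized Bernoulli log-likelihood phi1 (larger is better).

    ``beta`` is the (K+1)-vector (intercept first); ``beta_cov`` holds the
    covariate coefficients when ``covariates`` is given.
    """
    F = compute_component_scores(Xstd, groups, w)
    eta = beta[0] + F @ beta[1:]
    pen = 0.5 * config.lambda_prot * float(beta[1:] @ beta[1:])
    if config.penalize_intercept:
        pen += 0.5 * config.lambda_prot * float(beta[0] ** 2)
    if covariates is not None:
        if beta_cov is None:
            raise DataError("beta_cov required when covariates are supplied")
        eta = eta + covariates @ beta_cov
        if config.penalize_covariates:
            pen += 0.5 * config.lambda_prot * float(beta_cov @ beta_cov)
    pen += 0.5 * config.lambda_pep * float(w @ w)
    return _bernoulli_loglik(np.asarray(eta), np.asarray(y, dtype=float)) - pen


@dataclass(frozen=True)
class HisComFit:
    """A fitted hierarchical component model.

    ``beta`` stores the intercept followed by the K path coefficients.  The
    sign convention sum_i w_ki >= 0 (first weight breaking ties) is applied
    per protein after convergence, with beta_k flipped in compensation, so
    reported loadings are comparable across fits while predictions are
    untouched.
    """

    peptide_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    pep_protein_ids: tuple[str, ...]
    w: np.ndarray
    beta: np.ndarray
    beta_age: float | None
    beta_sex: float | None
    standardizer: Standardizer | None
    config: ModelConfig
    objective_trace: tuple[float, ...]
    converged: bool
    n_iter: int
    F: np.ndarray | None = None
    inner_traces: tuple[tuple[float, ...], ...] | None = None

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def has_covariates(self) -> bool:
        return self.beta_age is not None

    def groups(self) -> list[np.ndarray]:
        cols: dict[str, list[int]] = {}
        for i, prot in enumerate(self.pep_protein_ids):
            cols.setdefault(prot, []).append(i)
        return [np.asarray(cols[p], dtype=np.intp) for p in self.protein_ids]

    def linear_predictor(self, Xstd: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        F = compute_component_scores(Xstd, self.groups(), self.w)
        eta = self.beta[0] + F @ self.beta[1:]
        if self.has_covariates:
            if covariates is None:
                raise DataError("model was fitted with covariates; age/sex required")
            eta = eta + covariates @ np.array([self.beta_age, self.beta_sex])
        return eta


def _apply_sign_convention(
    w: np.ndarray, beta: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    w = w.copy()
    beta = beta.copy()
    for k, idx in enumerate(groups):
        s = w[idx].sum()
        ref = s if s != 0 else (w[idx][0] if len(idx) else 1.0)
        if ref < 0:
            w[idx] = -w[idx]
            beta[k + 1] = -beta[k + 1]
    return w, beta


def fit_hiscom_arrays(
    Xstd: np.ndarray,
    y: np.ndarray,
    groups: Sequence[np.ndarray],
    config: ModelConfig,
    covariates: np.ndarray | None = None,
    w0: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    track_inner: bool = False,
):
    """Core IRLS + ALS solver on plain arrays.

    Returns ``(w, beta, beta_cov, objective_trace, converged, n_iter,
    inner_traces)`` where ``beta`` is the (K+1) intercept-first vector and
    ``beta_cov`` the covariate coefficients (empty array without covariates).
    Standardization, identifier bookkeeping and the sign convention live in
    :func:`irls_als_fit`; this function is the hot path reused by permutation
    refits and simulations.
    """
    Xstd = np.asarray(Xstd, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xstd.shape
    K = len(groups)
    pep_protein = _groups_to_protein_index(groups, p)
    n_cov = 0 if covariates is None else covariates.shape[1]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)

    # beta penalty mask over [intercept, K paths, covariates]
    mask = np.concatenate([
        [config.penalize_intercept],
        np.ones(K, dtype=bool),
        np.full(n_cov, config.penalize_covariates),
    ]).astype(bool)

    sizes = np.array([len(idx) for idx in groups], dtype=float)
    if w0 is None:
        w = (1.0 / np.sqrt(sizes))[pep_protein]
    else:
        w = np.asarray(w0, dtype=float).copy()
    if beta0 is None:
        ybar = min(max(float(y.mean()), 0.01), 0.99)
        beta_all = np.zeros(1 + K + n_cov)
        beta_all[0] = np.log(ybar / (1.0 - ybar))
    else:
        beta_all = np.asarray(beta0, dtype=float).copy()

    ones = np.ones((n, 1))

    def eta_of(w_, beta_all_):
        F = compute_component_scores(Xstd, groups, w_)
        eta = beta_all_[0] + F @ beta_all_[1 : 1 + K]
        if n_cov:
            eta = eta + covariates @ beta_all_[1 + K :]
        return F, eta

    def phi1_of(w_, beta_all_, eta):
        pen = 0.5 * config.lambda_pep * float(w_ @ w_)
        pen += 0.5 * config.lambda_prot * float(beta_all_[mask] @ beta_all_[mask])
        return _bernoulli_loglik(eta, y) - pen

    F, eta = eta_of(w, beta_all)
    phi1 = phi1_of(w, beta_all, eta)
    trace = [phi1]
    inner_traces: list[tuple[float, ...]] = []
    converged = False
    n_iter = 0

    for outer in range(config.max_outer_iter):
        n_iter = outer + 1
        mu = np.clip(_expit(eta), MU_EPS, 1.0 - MU_EPS)
        v = np.maximum(mu * (1.0 - mu), V_FLOOR)
        z = eta + (y - mu) / v

        w_prev, beta_prev = w.copy(), beta_all.copy()

        def phi2_of(F_, beta_all_, w_):
            resid = z - (
                beta_all_[0]
                + F_ @ beta_all_[1 : 1 + K]
                + (covariates @ beta_all_[1 + K :] if n_cov else 0.0)
            )
            pen = config.lambda_pep * float(w_ @ w_)
            pen += config.lambda_prot * float(beta_all_[mask] @ beta_all_[mask])
            return float(v @ resid**2) + pen

        inner_vals = [phi2_of(F, beta_all, w)] if track_inner else []
        phi2 = phi2_of(F, beta_all, w)
        for _ in range(config.max_inner_iter):
            F_design = np.hstack([ones, F, covariates]) if n_cov else np.hstack([ones, F])
            beta_all = beta_update(F_design, z, v, config.lambda_prot, mask)
            if track_inner:
                inner_vals.append(phi2_of(F, beta_all, w))
            offset = np.full(n, beta_all[0])
            if n_cov:
                offset += covariates @ beta_all[1 + K :]
            w = weight_update(
                Xstd, pep_protein, z, v, beta_all[1 : 1 + K], offset, config.lambda_pep
            )
            F = compute_component_scores(Xstd, groups, w)
            phi2_new = phi2_of(F, beta_all, w)
            if track_inner:
                inner_vals.append(phi2_new)
            if abs(phi2 - phi2_new) <= config.tol * (abs(phi2) + 1e-12):
                phi2 = phi2_new
                break
            phi2 = phi2_new
        if track_inner:
            inner_traces.append(tuple(inner_vals))

        # Step-halving guard: the composite inner-ALS step is not guaranteed
        # to increase phi1 far from the optimum; back off along the segment,
        # and if that fails fall back to individually line-searched single
        # block updates (each block step is H^-1 grad, an ascent direction).
        slack = 1e-12 * (abs(phi1) + 1.0)

        def _search(base_val, w_from, beta_from, w_to, beta_to):
            """Largest halved step along the segment strictly increasing
            phi1; falls back to the start point when none improves."""
            step = 1.0
            while step > 1e-12:
                w_t = w_from + step * (w_to - w_from)
                b_t = beta_from + step * (beta_to - beta_from)
                _, eta_t = eta_of(w_t, b_t)
                val = phi1_of(w_t, b_t, eta_t)
                if val > base_val + slack:
                    return w_t, b_t, val
                step *= 0.5
            return w_from, beta_from, base_val

        w, beta_all, phi1_new = _search(phi1, w_prev, beta_prev, w, beta_all)
        if phi1_new <= phi1:
            # composite step made no progress: safeguarded single block steps
            w, beta_all = w_prev.copy(), beta_prev.copy()
            F = compute_component_scores(Xstd, groups, w)
            F_design = np.hstack([ones, F, covariates]) if n_cov else np.hstack([ones, F])
            beta_target = beta_update(F_design, z, v, config.lambda_prot, mask)
            w, beta_all, phi1_new = _search(phi1, w, beta_all, w, beta_target)
            offset = np.full(n, beta_all[0])
            if n_cov:
                offset += covariates @ beta_all[1 + K :]
            w_target = weight_update(
                Xstd, pep_protein, z, v, beta_all[1 : 1 + K], offset, config.lambda_pep
            )
            w, beta_all, phi1_new = _search(phi1_new, w, beta_all, w_target, beta_all)
        F, eta = eta_of(w, beta_all)
        trace.append(phi1_new)
        rel = abs(phi1_new - phi1) / (abs(phi1) + 1e-12)
        phi1 = phi1_new
        if rel < config.tol:
            converged = True
            break

    beta = beta_all[: 1 + K]
    beta_cov = beta_all[1 + K :]
    return w, beta, beta_cov, tuple(trace), converged, n_iter, tuple(inner_traces) or None


def irls_als_fit(
    X: PeptideMatrix,
    pheno: Phenotype | None,
    hierarchy: Hierarchy,
    config: ModelConfig | None = None,
    y: np.ndarray | None = None,
    use_covariates: bool = True,
    track_inner: bool = False,
    standardizer: Standardizer | None = None,
) -> HisComFit:
    """Fit the hierarchical component model.

    Parameters
    ----------
    X, pheno, hierarchy
        Peptide matrix, phenotype table (aligned by sample id) and
        peptide -> protein map.  ``pheno`` may be omitted when ``y`` is given
        directly, in which case no covariates are used.
    use_covariates
        Include age and sex columns in the outcome model (the default, as in
        the prediction equation).
    standardizer
        Reuse previously learned training statistics instead of fitting them
        on ``X`` (used when scoring held-out data pipelines refit on splits).
    """
    config = config or ModelConfig()
    if pheno is not None:
        pheno = pheno.aligned_to(X.sample_ids)
        y_arr = pheno.response.astype(float)
        covariates = pheno.covariate_matrix() if use_covariates else None
    else:
        if y is None:
            raise DataError("either pheno or y must be provided")
        y_arr = np.asarray(y, dtype=float)
        covariates = None
    if y_arr.shape != (X.n_samples,):
        raise DataError("response length does not match the peptide matrix")
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise DataError("need at least 2 samples in each response class")

    std = standardizer or standardize_fit(X)
    Xstd = std.transform(X.values) if std.peptide_ids == X.peptide_ids else standardize_apply(std, X)
    protein_ids, groups = hierarchy.groups_for(X.peptide_ids)

    w, beta, beta_cov, trace, converged, n_iter, inner = fit_hiscom_arrays(
        Xstd, y_arr, groups, config, covariates=covariates, track_inner=track_inner
    )
    if not converged:
        warnings.warn(
            f"HisCoM did not converge in {config.max_outer_iter} outer iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    w, beta = _apply_sign_convention(w, beta, groups)
    F = np.hstack([np.ones((X.n_samples, 1)), compute_component_scores(Xstd, groups, w)])
    return HisComFit(
        peptide_ids=X.peptide_ids,
        protein_ids=protein_ids,
        pep_protein_ids=tuple(hierarchy.mapping[p] for p in X.peptide_ids),
        w=w,
        beta=beta,
        beta_age=float(beta_cov[0]) if covariates is not None else None,
        beta_sex=float(beta_cov[1]) if covariates is not None else None,
        standardizer=std,
        config=config,
        objective_trace=trace,
        converged=converged,
        n_iter=n_iter,
        F=F,
        inner_traces=inner,
    )


def predict_proba(
    fit: HisComFit, Xnew: PeptideMatrix, pheno_new: Phenotype | None = None
) -> np.ndarray:
    """Predicted response probabilities pi_j for new samples.

    Columns are matched to the training peptides by identifier and
    standardized with the stored training statistics.
    """
    if set(Xnew.peptide_ids) != set(fit.peptide_ids):
        unknown = set(Xnew.peptide_ids) - set(fit.peptide_ids)
        missing = set(fit.peptide_ids) - set(Xnew.peptide_ids)
        parts = []
        if unknown:
            parts.append(f"unknown peptide columns: {sorted(unknown)}")
        if missing:
            parts.append(f"missing peptide columns: {sorted(missing)}")
        raise DataError("; ".join(parts))
    Xnew = Xnew.subset_peptides(fit.peptide_ids)
    if fit.standardizer is None:
        raise DataError("fit carries no standardizer; cannot score new samples")
    Xstd = standardize_apply(fit.standardizer, Xnew)
    covariates = None
    if fit.has_covariates:
        if pheno_new is None:
            raise DataError("model was fitted with covariates; phenotype table required")
        covariates = pheno_new.aligned_to(Xnew.sample_ids).covariate_matrix()
    return _expit(fit.linear_predictor(Xstd, covariates))
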