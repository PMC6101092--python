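"""Splits, AUC scoring and logistic baselines for model comparison.

The cohort workflow holds out a ratio-preserving test set (e.g. 39 of 115
samples), then repeatedly halves the remainder into training and validation
sets that retain the positive:negative ratio.  Discrimination is measured by
the area under the ROC curve via the Mann-Whitney pair statistic, and the
hierarchical component model is compared against two baselines on raw peptide
columns: an unpenalized logistic regression (GLM) and a ridge-penalized one
(GLMwR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .containers import DataError, Hierarchy, PeptideMatrix, Phenotype
from .core import (
    MU_EPS,
    ModelConfig,
    Standardizer,
    _expit,
    fit_hiscom_arrays,
    standardize_fit,
)

__all__ = [
    "SplitPlan",
    "BaselineFit",
    "ComparisonResult",
    "stratified_test_split",
    "train_validation_split",
    "split_cohort",
    "auc",
    "fit_glm",
    "fit_glm_ridge",
    "compare_models",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SplitPlan:
    """Index partition of a cohort into test / train / validation."""

    test_indices: np.ndarray
    train_indices: np.ndarray
    validation_indices: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("test_indices", "train_indices", "validation_indices"):
            arr = np.asarray(getattr(self, name), dtype=np.intp)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        parts = [self.test_indices, self.train_indices, self.validation_indices]
        flat = np.concatenate(parts)
        if len(np.unique(flat)) != len(flat):
            raise DataError("split partitions overlap")

    def class_counts(self, y: np.ndarray) -> dict[str, tuple[int, int]]:
        y = np.asarray(y)
        out = {}
        for name, idx in (
            ("test", self.test_indices),
            ("train", self.train_indices),
            ("validation", self.validation_indices),
        ):
            out[name] = (int((y[idx] == 1).sum()), int((y[idx] == 0).sum()))
        return out


def stratified_test_split(y: np.ndarray, test_n: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw a class-ratio-preserving test set of ``test_n`` samples.

    Positives are allocated as round(test_n * n_pos / n) with halves rounded
    away from zero (39 of 115 with 40 positives gives 14 positive and 25
    negative test samples); members are sampled uniformly without replacement
    within each class.  Returns ``(test_indices, rest_indices)``.
    """
    y = np.asarray(y)
    n = len(y)
    if not (0 < test_n < n):
        raise DataError(f"test_n must be in (0, {n}), got {test_n}")
    rng = _rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("both response classes must be present")
    n_pos_test = _round_half_away(test_n * len(pos) / n)
    n_neg_test = test_n - n_pos_test
    if n_pos_test < 1 or n_neg_test < 1:
        raise DataError("a class would receive 0 test samples")
    if n_pos_test >= len(pos) or n_neg_test >= len(neg):
        raise DataError("a class would be exhausted by the test set")
    test = np.concatenate(
        [
            rng.choice(pos, size=n_pos_test, replace=False),
            rng.choice(neg, size=n_neg_test, replace=False),
        ]
    )
    test.sort()
    rest = np.setdiff1d(np.arange(n), test)
    return test, rest


def train_validation_split(
    y: np.ndarray, indices: np.ndarray | None = None, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Halve a sample set into train/validation, preserving the class ratio.

    Odd per-class counts put the extra member in the training or validation
    half at random (seeded).  Classes with fewer than 2 members are an error.
    """
    y = np.asarray(y)
    indices = np.arange(len(y)) if indices is None else np.asarray(indices, dtype=np.intp)
    rng = _rng(seed)
    train_parts, val_parts = [], []
    for cls in (1, 0):
        members = indices[y[indices] == cls]
        if len(members) < 2:
            raise DataError(f"class {cls} has fewer than 2 samples; cannot halve")
        members = rng.permutation(members)
        half = len(members) // 2
        if len(members) % 2 == 1 and rng.random() < 0.5:
            half += 1
        train_parts.append(members[:half])
        val_parts.append(members[half:])
    train = np.sort(np.concatenate(train_parts))
    validation = np.sort(np.concatenate(val_parts))
    return train, validation


def split_cohort(y: np.ndarray, test_n: int, seed=None) -> SplitPlan:
    """Full three-way split: test hold-out, then train/validation halves."""
    rng = _rng(seed)
    test, rest = stratified_test_split(y, test_n, rng)
    train, validation = train_validation_split(y, rest, rng)
    return SplitPlan(test, train, validation, seed=seed if isinstance(seed, int) else None)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals (#{pos > neg pairs} + 0.5 #{ties}) / (n_pos * n_neg); ties are
    handled through midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must have the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class BaselineFit:
    """A (possibly ridge-penalized) logistic regression on peptide columns.

    ``coef`` is intercept-first, then one coefficient per peptide column,
    then the covariate coefficients.  Non-convergence (separation, singular
    working systems) is a reported state, not an error: ``coef`` then holds
    the last finite iterate.
    """

    coef: np.ndarray
    n_features: int
    n_covariates: int
    lam: float
    converged: bool
    standardizer: Standardizer | None = None

    def linear_predictor(self, X: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        eta = self.coef[0] + X @ self.coef[1 : 1 + self.n_features]
        if self.n_covariates:
            if covariates is None:
                raise DataError("baseline was fitted with covariates; covariates required")
            eta = eta + covariates @ self.coef[1 + self.n_features :]
        return eta

    def predict_proba(self, X: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        return _expit(self.linear_predictor(X, covariates))


_BLOWUP = 1e8


def _logistic_irls(
    A: np.ndarray, y: np.ndarray, penalty: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """IRLS for a logistic model with a diagonal ridge ``penalty``.

    Divergence is detected by coefficient blow-up or a singular working
    system; the last finite iterate is returned with ``converged=False``.
    """
    n, d = A.shape
    beta = np.zeros(d)
    ybar = min(max(float(y.mean()), 0.01), 0.99)
    beta[0] = np.log(ybar / (1 - ybar))
    converged = False
    for _ in range(max_iter):
        eta = A @ beta
        mu = np.clip(_expit(eta), MU_EPS, 1 - MU_EPS)
        v = mu * (1 - mu)
        z = eta + (y - mu) / v
        G = A.T @ (A * v[:, None])
        G[np.diag_indices_from(G)] += penalty
        rhs = A.T @ (v * z)
        try:
            new = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            new, *_ = np.linalg.lstsq(G, rhs, rcond=None)
            beta_new = new
            if np.all(np.isfinite(beta_new)):
                beta = beta_new
            break
        if not np.all(np.isfinite(new)) or np.max(np.abs(new)) > _BLOWUP:
            break
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol * (1 + np.max(np.abs(beta))):
            converged = True
            break
    return beta, converged


def _assemble_design(
    X: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, int]:
    n = X.shape[0]
    parts = [np.ones((n, 1)), X]
    n_cov = 0
    if covariates is not None:
        parts.append(np.asarray(covariates, dtype=float))
        n_cov = covariates.shape[1]
    return np.hstack(parts), n_cov


def fit_glm(
    X: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> BaselineFit:
    """Unpenalized logistic regression on peptide columns (plus covariates)."""
    A, n_cov = _assemble_design(np.asarray(X, dtype=float), covariates)
    coef, converged = _logistic_irls(A, np.asarray(y, dtype=float), np.zeros(A.shape[1]))
    return BaselineFit(coef, X.shape[1], n_cov, 0.0, converged)


def fit_glm_ridge(
    X: np.ndarray, y: np.ndarray, lam: float, covariates: np.ndarray | None = None
) -> BaselineFit:
    """Ridge logistic regression; intercept and covariates are unpenalized."""
    if lam < 0:
        raise ValueError("ridge parameter must be nonnegative")
    X = np.asarray(X, dtype=float)
    A, n_cov = _assemble_design(X, covariates)
    penalty = np.concatenate([[0.0], np.full(X.shape[1], lam), np.zeros(n_cov)])
    coef, converged = _logistic_irls(A, np.asarray(y, dtype=float), penalty)
    return BaselineFit(coef, X.shape[1], n_cov, float(lam), converged)


DEFAULT_RIDGE_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def _select_ridge_lambda(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    cov_tr: np.ndarray | None,
    grid: Sequence[float],
    seed,
) -> float:
    """Grid-search lambda by AUC on an inner ratio-preserving half-split."""
    rng = _rng(seed)
    inner_tr, inner_va = train_validation_split(ytr, seed=rng)
    best_lam, best_auc = grid[0], -np.inf
    for lam in grid:
        fit = fit_glm_ridge(
            Xtr[inner_tr],
            ytr[inner_tr],
            lam,
            covariates=None if cov_tr is None else cov_tr[inner_tr],
        )
        scores = fit.predict_proba(
            Xtr[inner_va], None if cov_tr is None else cov_tr[inner_va]
        )
        try:
            a = auc(scores, ytr[inner_va])
        except DataError:
            continue
        if a > best_auc:
            best_auc, best_lam = a, lam
    return best_lam


@dataclass(frozen=True)
class ComparisonResult:
    """Per-method AUC on one partition for one protein subset."""

    aucs: dict[str, float]
    converged: dict[str, bool]
    partition: str
    protein_subset: tuple[str, ...]
    glmwr_lambda: float


def compare_models(
    X: PeptideMatrix,
    pheno: Phenotype,
    hierarchy: Hierarchy,
    config: ModelConfig,
    split: SplitPlan,
    protein_subset: Sequence[str],
    partition: str = "validation",
    glmwr_lambda: float | None = None,
    glmwr_grid: Sequence[float] = DEFAULT_RIDGE_GRID,
    use_covariates: bool = True,
    seed=None,
) -> ComparisonResult:
    """Fit HisCoM, GLM and GLMwR on the training split and score a partition.

    Only the peptides of ``protein_subset`` (plus age and sex) enter each
    model.  When ``glmwr_lambda`` is None it is grid-searched by AUC on an
    inner half-split of the training samples, so the baseline is not rigged
    by an arbitrary fixed value.
    """
    protein_subset = tuple(protein_subset)
    if not protein_subset:
        raise DataError("protein subset must not be empty")
    known = set(hierarchy.proteins)
    for prot in protein_subset:
        if prot not in known:
            raise DataError(f"protein {prot!r} not in hierarchy")
    peptides = [p for p in X.peptide_ids if hierarchy.mapping.get(p) in set(protein_subset)]
    if not peptides:
        raise DataError("protein subset covers no peptide columns")
    Xs = X.subset_peptides(peptides)
    pheno = pheno.aligned_to(X.sample_ids)
    y = pheno.response.astype(float)
    cov = pheno.covariate_matrix() if use_covariates else None

    tr = split.train_indices
    ev = {"test": split.test_indices, "train": tr, "validation": split.validation_indices}[
        partition
    ]
    std = standardize_fit(Xs.subset_samples(tr))
    Xstd = std.transform(Xs.values)
    _, groups = hierarchy.groups_for(Xs.peptide_ids)
    cov_tr = None if cov is None else cov[tr]

    w, beta, beta_cov, _, conv_h, _, _ = fit_hiscom_arrays(
        Xstd[tr], y[tr], groups, config, covariates=cov_tr
    )
    F_ev = np.empty((len(ev), len(groups)))
    for k, idx in enumerate(groups):
        F_ev[:, k] = Xstd[np.ix_(ev, idx)] @ w[idx]
    eta_h = beta[0] + F_ev @ beta[1:]
    if cov is not None:
        eta_h = eta_h + cov[ev] @ beta_cov

    glm = fit_glm(Xstd[tr], y[tr], covariates=cov_tr)
    scores_glm = glm.predict_proba(Xstd[ev], None if cov is None else cov[ev])

    lam = glmwr_lambda
    if lam is None:
        lam = _select_ridge_lambda(Xstd[tr], y[tr], cov_tr, glmwr_grid, seed)
    glmwr = fit_glm_ridge(Xstd[tr], y[tr], lam, covariates=cov_tr)
    scores_glmwr = glmwr.predict_proba(Xstd[ev], None if cov is None else cov[ev])

    return ComparisonResult(
        aucs={
            "hiscom": auc(eta_h, y[ev]),
            "glm": auc(scores_glm, y[ev]),
            "glmwr": auc(scores_glmwr, y[ev]),
        },
        converged={"hiscom": conv_h, "glm": glm.converged, "glmwr": glmwr.converged},
        partition=partition,
        protein_subset=protein_subset,
        glmwr_lambda=float(lam),
    )
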