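"""Permutation significance of protein path coefficients.

The null distribution of each protein's path coefficient beta_k is built by
shuffling the drug-response labels across subjects (a permutation of the
label vector automatically preserves the positive:negative ratio) and
refitting the full model per shuffle.  Two-sided p-values compare |beta_k|
against the permuted values with an add-one correction so p can never be 0:

    p_k = (1 + #{b : |beta_k^(b)| >= |beta_k^obs|}) / (B + 1) .

A consistency screen repeats the test on many ratio-preserving training
halves and reports how often each protein reaches significance — proteins
that are repeatedly significant are the biomarker candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import DataError, Hierarchy, PeptideMatrix, Phenotype
from .core import ModelConfig, fit_hiscom_arrays, standardize_fit
from .evaluation import train_validation_split

__all__ = [
    "PermutationResult",
    "SelectionReport",
    "permutation_test",
    "select_significant",
    "replicate_selection",
]


@dataclass(frozen=True)
class PermutationResult:
    protein_ids: tuple[str, ...]
    beta_obs: np.ndarray
    beta_null: np.ndarray  # B_effective x K
    p_values: np.ndarray
    B: int
    n_failed: int
    seed: int | None
    alternative: str

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


def _fit_paths(Xstd, y, groups, config, covariates):
    w, beta, _, _, converged, _, _ = fit_hiscom_arrays(
        Xstd, y, groups, config, covariates=covariates
    )
    # report on the sign-convention scale so observed and permuted
    # coefficients are comparable
    for k, idx in enumerate(groups):
        s = w[idx].sum()
        ref = s if s != 0 else w[idx][0]
        if ref < 0:
            beta[k + 1] = -beta[k + 1]
    return beta[1:], converged


def permutation_test(
    X: PeptideMatrix,
    pheno: Phenotype,
    hierarchy: Hierarchy,
    config: ModelConfig | None = None,
    B: int = 1000,
    seed: int | None = None,
    use_covariates: bool = True,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Label-permutation test of the protein path coefficients.

    Each of the ``B`` permutations refits the full model (weights and path
    coefficients jointly) on the shuffled labels.  Permuted refits that fail
    to converge are excluded with a warning; more than 10% failures abort.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    config = config or ModelConfig()
    pheno = pheno.aligned_to(X.sample_ids)
    y = pheno.response.astype(float)
    covariates = pheno.covariate_matrix() if use_covariates else None
    std = standardize_fit(X)
    Xstd = std.transform(X.values)
    protein_ids, groups = hierarchy.groups_for(X.peptide_ids)

    beta_obs, conv = _fit_paths(Xstd, y, groups, config, covariates)
    if not conv:
        warnings.warn("observed-data fit did not converge", RuntimeWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    null_rows = []
    n_failed = 0
    for _ in range(B):
        perm = rng.permutation(len(y))
        beta_b, conv_b = _fit_paths(Xstd, y[perm], groups, config, covariates)
        if conv_b:
            null_rows.append(beta_b)
        else:
            n_failed += 1
    if n_failed > 0.1 * B:
        raise RuntimeError(f"{n_failed}/{B} permutation refits failed to converge")
    if n_failed:
        warnings.warn(
            f"excluded {n_failed} non-converged permutation refits", RuntimeWarning, stacklevel=2
        )
    beta_null = np.asarray(null_rows)
    B_eff = beta_null.shape[0]
    if alternative == "two-sided":
        exceed = (np.abs(beta_null) >= np.abs(beta_obs)).sum(axis=0)
    else:
        exceed = (beta_null >= beta_obs).sum(axis=0)
    p_values = (1.0 + exceed) / (B_eff + 1.0)
    return PermutationResult(
        protein_ids=protein_ids,
        beta_obs=beta_obs,
        beta_null=beta_null,
        p_values=p_values,
        B=B_eff,
        n_failed=n_failed,
        seed=seed,
        alternative=alternative,
    )


def select_significant(result: PermutationResult, alpha: float = 0.05) -> list[str]:
    """Proteins with p < alpha, in ascending-p order (stable ties)."""
    order = np.argsort(result.p_values, kind="stable")
    return [result.protein_ids[k] for k in order if result.p_values[k] < alpha]


@dataclass(frozen=True)
class SelectionReport:
    protein_ids: tuple[str, ...]
    frequencies: np.ndarray
    selected: tuple[str, ...]
    alpha: float
    frequency_threshold: float
    n_replicates: int
    seed: int | None


def replicate_selection(
    X: PeptideMatrix,
    pheno: Phenotype,
    hierarchy: Hierarchy,
    config: ModelConfig | None = None,
    n_replicates: int = 100,
    B: int = 1000,
    alpha: float = 0.05,
    frequency_threshold: float = 0.5,
    seed: int | None = None,
    use_covariates: bool = True,
) -> SelectionReport:
    """Consistency screen over repeated ratio-preserving training halves.

    Each replicate splits the cohort into training/validation halves that
    retain the class ratio, runs the permutation test on the training half,
    and records which proteins reach p < alpha.  Proteins significant in at
    least ``frequency_threshold`` of the replicates are selected.
    """
    if n_replicates < 1:
        raise DataError("n_replicates must be at least 1")
    config = config or ModelConfig()
    pheno = pheno.aligned_to(X.sample_ids)
    rng = np.random.default_rng(seed)
    protein_ids, _ = hierarchy.groups_for(X.peptide_ids)
    hits = np.zeros(len(protein_ids))
    for _ in range(n_replicates):
        tr, _va = train_validation_split(pheno.response, seed=rng)
        res = permutation_test(
            X.subset_samples(tr),
            pheno.subset(tr),
            hierarchy,
            config,
            B=B,
            seed=int(rng.integers(2**31 - 1)),
            use_covariates=use_covariates,
        )
        hits += (res.p_values < alpha).astype(float)
    freq = hits / n_replicates
    selected = tuple(
        protein_ids[k]
        for k in np.argsort(-freq, kind="stable")
        if freq[k] >= frequency_threshold
    )
    return SelectionReport(
        protein_ids=protein_ids,
        frequencies=freq,
        selected=selected,
        alpha=alpha,
        frequency_threshold=frequency_threshold,
        n_replicates=n_replicates,
        seed=seed,
    )
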