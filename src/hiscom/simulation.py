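"""Synthetic MRM-MS cohorts and the simulation comparison study.

Peptide ratios are drawn from a zero-mean, unit-variance multivariate normal
with block compound-symmetric correlation: rho within each protein's peptide
block (targeted peptide panels show strong within-protein correlation) and a
configurable value (default 0) between proteins.  Binary responses follow the
hierarchical truth

    logit(pi_j) = beta_0 + sum_k (sum_i x_jki omega_i) beta_k
                  + AGE_j beta_age + SEX_j beta_sex ,
    y_j ~ Bernoulli(pi_j) ,

with age uniform on a configured range and sex a 0/1 code drawn with a
configured male fraction.  The study runner keeps the peptide matrix — and
hence pi_1..pi_n — fixed, redraws y each replicate, fits the hierarchical
component model and the two logistic baselines, and records one AUC per
method per replicate.

Two ready-made designs mirror the published comparison regimes: ``model1``
has two associated proteins (3 and 2 peptides); ``model2`` pairs a 2-peptide
associated protein with a 7-peptide null protein, the regime where collapsing
peptides into protein components pays off most.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .containers import DataError, Hierarchy, PeptideMatrix, Phenotype
from .core import ModelConfig, _expit
from .evaluation import (
    DEFAULT_RIDGE_GRID,
    SplitPlan,
    compare_models,
    train_validation_split,
)

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "model1_spec",
    "model2_spec",
    "simulate_peptides",
    "true_linear_predictor",
    "simulate_responses",
    "run_simulation_study",
    "generate_cohort",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters of a synthetic cohort.

    ``weights`` holds one loading per peptide (defaults to 1/sqrt(T_k) within
    protein k); ``betas`` one path coefficient per protein.  ``rho`` is the
    within-protein peptide correlation, ``rho_between`` the across-protein
    value.
    """

    protein_sizes: tuple[int, ...]
    betas: tuple[float, ...]
    weights: tuple[float, ...] | None = None
    beta0: float = -1.4
    beta_age: float = 0.01
    beta_sex: float = 0.3
    rho: float = 0.7
    rho_between: float = 0.0
    n_samples: int = 115
    age_range: tuple[float, float] = (34.0, 84.0)
    male_fraction: float = 101 / 115
    n_replicates: int = 1000

    def __post_init__(self) -> None:
        if not self.protein_sizes or any(t < 1 for t in self.protein_sizes):
            raise DataError("protein sizes must be positive")
        if len(self.betas) != len(self.protein_sizes):
            raise DataError("one path coefficient per protein required")
        if not (0 <= self.rho < 1):
            raise DataError("rho must be in [0, 1)")
        if self.weights is not None and len(self.weights) != self.n_peptides:
            raise DataError("one weight per peptide required")
        if self.n_replicates < 1:
            raise DataError("n_replicates must be at least 1")
        if not (0 <= self.male_fraction <= 1):
            raise DataError("male_fraction must be in [0, 1]")

    @property
    def n_peptides(self) -> int:
        return sum(self.protein_sizes)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_sizes)

    def effective_weights(self) -> np.ndarray:
        if self.weights is not None:
            return np.asarray(self.weights, dtype=float)
        return np.concatenate(
            [np.full(t, 1.0 / np.sqrt(t)) for t in self.protein_sizes]
        )

    def hierarchy(self) -> Hierarchy:
        pairs = []
        i = 0
        for k, t in enumerate(self.protein_sizes):
            for _ in range(t):
                pairs.append((f"pep{i:03d}", f"prot{k}"))
                i += 1
        return Hierarchy.from_pairs(pairs)


def model1_spec(**overrides) -> SimulationSpec:
    """Two associated proteins of 3 and 2 peptides (higher-signal regime)."""
    base = SimulationSpec(protein_sizes=(3, 2), betas=(1.2, 1.2), beta0=-1.75)
    return replace(base, **overrides)


def model2_spec(**overrides) -> SimulationSpec:
    """A 2-peptide associated protein plus a 7-peptide null protein."""
    base = SimulationSpec(protein_sizes=(2, 7), betas=(1.4, 0.0), beta0=-1.55)
    return replace(base, **overrides)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _block_correlation(sizes: Sequence[int], rho: float, rho_between: float) -> np.ndarray:
    p = sum(sizes)
    C = np.full((p, p), rho_between)
    start = 0
    for t in sizes:
        C[start : start + t, start : start + t] = rho
        start += t
    np.fill_diagonal(C, 1.0)
    return C


def simulate_peptides(
    spec: SimulationSpec, seed=None
) -> tuple[PeptideMatrix, np.ndarray, np.ndarray]:
    """Draw the peptide matrix and covariates of one synthetic cohort.

    Returns ``(X, age, sex)``; peptide values are standard normal with the
    spec's block correlation, ages uniform on the configured range, sex 1
    with probability ``male_fraction``.
    """
    rng = _rng(seed)
    C = _block_correlation(spec.protein_sizes, spec.rho, spec.rho_between)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise DataError(
            "correlation structure is not positive definite for these block sizes"
        ) from None
    Z = rng.standard_normal((spec.n_samples, spec.n_peptides))
    values = Z @ L.T
    X = PeptideMatrix(
        tuple(f"S{j:04d}" for j in range(spec.n_samples)),
        tuple(f"pep{i:03d}" for i in range(spec.n_peptides)),
        values,
    )
    age = rng.uniform(*spec.age_range, size=spec.n_samples)
    sex = (rng.random(spec.n_samples) < spec.male_fraction).astype(int)
    return X, age, sex


def true_linear_predictor(
    spec: SimulationSpec, values: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """eta_j of the generating model at the spec's true coefficients."""
    w = spec.effective_weights()
    eta = np.full(values.shape[0], spec.beta0)
    start = 0
    for t, beta_k in zip(spec.protein_sizes, spec.betas):
        eta += (values[:, start : start + t] @ w[start : start + t]) * beta_k
        start += t
    return eta + age * spec.beta_age + sex * spec.beta_sex


def simulate_responses(
    spec: SimulationSpec, values: np.ndarray, age: np.ndarray, sex: np.ndarray, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw y_j ~ Bernoulli(pi_j); returns ``(y, pi)``."""
    rng = _rng(seed)
    pi = _expit(true_linear_predictor(spec, values, age, sex))
    y = (rng.random(len(pi)) < pi).astype(int)
    return y, pi


@dataclass(frozen=True)
class SimulationResult:
    methods: tuple[str, ...]
    aucs: dict[str, np.ndarray]
    n_failed: int
    eval_scheme: str
    seed: int | None

    @property
    def mean_auc(self) -> dict[str, float]:
        return {m: float(np.mean(self.aucs[m])) for m in self.methods}

    @property
    def n_replicates(self) -> int:
        return len(next(iter(self.aucs.values())))


def run_simulation_study(
    spec: SimulationSpec,
    config: ModelConfig | None = None,
    eval_scheme: str = "holdout",
    seed: int | None = None,
    glmwr_lambda: float | None = None,
    glmwr_grid: Sequence[float] = DEFAULT_RIDGE_GRID,
) -> SimulationResult:
    """Repeatedly redraw responses at fixed pi and compare the three models.

    The peptide matrix (and therefore pi_1..pi_n) is generated once and held
    fixed; each replicate redraws y, fits HisCoM, GLM and GLMwR, and records
    one AUC per method.  ``eval_scheme`` is ``"holdout"`` (fit on a
    ratio-preserving half, score the other half; the default) or
    ``"insample"`` (fit and score on the full cohort).  Replicates whose fits
    fail (e.g. a degenerate class split) are dropped; more than 10% failures
    abort.
    """
    if eval_scheme not in ("holdout", "insample"):
        raise ValueError("eval_scheme must be 'holdout' or 'insample'")
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    X, age, sex = simulate_peptides(spec, rng)
    pi = _expit(true_linear_predictor(spec, X.values, age, sex))
    hierarchy = spec.hierarchy()
    methods = ("hiscom", "glm", "glmwr")
    aucs: dict[str, list[float]] = {m: [] for m in methods}
    n_failed = 0
    n = spec.n_samples
    for _ in range(spec.n_replicates):
        y = (rng.random(n) < pi).astype(int)
        try:
            pheno = Phenotype(X.sample_ids, y, age, sex)
            if eval_scheme == "holdout":
                tr, va = train_validation_split(y, seed=rng)
                split = SplitPlan(np.empty(0, dtype=np.intp), tr, va)
                part = "validation"
            else:
                idx = np.arange(n)
                split = SplitPlan(np.empty(0, dtype=np.intp), idx, np.empty(0, dtype=np.intp))
                part = "train"
            res = compare_models(
                X,
                pheno,
                hierarchy,
                config,
                split,
                hierarchy.proteins,
                partition=part,
                glmwr_lambda=glmwr_lambda,
                glmwr_grid=glmwr_grid,
                seed=rng,
            )
        except (DataError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for m in methods:
            aucs[m].append(res.aucs[m])
    if n_failed > 0.1 * spec.n_replicates:
        raise RuntimeError(f"{n_failed}/{spec.n_replicates} simulation replicates failed")
    return SimulationResult(
        methods=methods,
        aucs={m: np.asarray(v) for m, v in aucs.items()},
        n_failed=n_failed,
        eval_scheme=eval_scheme,
        seed=seed,
    )


def _cohort_protein_sizes(n_proteins: int = 124, n_peptides: int = 231, max_size: int = 7) -> np.ndarray:
    """A protein-size vector emulating a targeted panel's nesting.

    Most proteins contribute one or two peptides, a few up to ``max_size``;
    sizes sum to ``n_peptides`` across ``n_proteins`` proteins.
    """
    if n_peptides < n_proteins:
        raise DataError("need at least one peptide per protein")
    sizes = np.ones(n_proteins, dtype=int)
    extra = n_peptides - n_proteins
    frac = 0.5
    while extra > 0:
        take = max(1, min(extra, int(round(n_proteins * frac))))
        eligible = np.flatnonzero(sizes < max_size)[:take]
        if len(eligible) == 0:
            raise DataError("cannot satisfy size constraints; raise max_size")
        sizes[eligible] += 1
        extra -= len(eligible)
        frac /= 2.0
    return sizes


def generate_cohort(
    n_samples: int = 115,
    n_positive: int = 40,
    n_proteins: int = 124,
    n_peptides: int = 231,
    rho: float = 0.7,
    n_male: int | None = None,
    age_range: tuple[float, float] = (34.0, 84.0),
    seed: int | None = None,
) -> tuple[PeptideMatrix, Hierarchy, Phenotype]:
    """Emit a full synthetic cohort with the targeted-panel shape.

    Defaults emulate a 115-sample serum panel: 231 peptides nested in 124
    proteins, 40 positive / 75 negative responders, ages 34-84, 101 male /
    14 female.  Labels are assigned by count and are independent of the
    peptide values (a null cohort); use a :class:`SimulationSpec` to attach
    a true association.
    """
    rng = np.random.default_rng(seed)
    sizes = _cohort_protein_sizes(n_proteins, n_peptides)
    spec = SimulationSpec(
        protein_sizes=tuple(int(t) for t in sizes),
        betas=tuple(0.0 for _ in sizes),
        rho=rho,
        n_samples=n_samples,
        age_range=age_range,
    )
    X, age, _ = simulate_peptides(spec, rng)
    if n_male is None:
        n_male = int(round(n_samples * 101 / 115))
    sex = np.zeros(n_samples, dtype=int)
    sex[rng.choice(n_samples, size=n_male, replace=False)] = 1
    y = np.zeros(n_samples, dtype=int)
    y[rng.choice(n_samples, size=n_positive, replace=False)] = 1
    pheno = Phenotype(X.sample_ids, y, np.round(age), sex)
    return X, spec.hierarchy(), pheno
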