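"""Shared fixtures: tiny deterministic cohorts used across the suite."""

import numpy as np
import pytest

from hiscom.containers import Hierarchy, PeptideMatrix, Phenotype


@pytest.fixture
def tiny_hierarchy():
    """Two proteins with 2 and 3 peptides."""
    return Hierarchy.from_pairs(
        [("pepA1", "protA"), ("pepA2", "protA"),
         ("pepB1", "protB"), ("pepB2", "protB"), ("pepB3", "protB")]
    )


def make_cohort(n=40, seed=0, signal=1.0, hierarchy_sizes=(2, 3)):
    """A small synthetic cohort with a genuine association.

    Peptides of each protein share a latent factor; the response depends on
    the first protein's factor with strength ``signal``.
    """
    rng = np.random.default_rng(seed)
    cols, pairs = [], []
    factors = []
    for k, t in enumerate(hierarchy_sizes):
        f = rng.standard_normal(n)
        factors.append(f)
        for i in range(t):
            cols.append(0.8 * f + 0.6 * rng.standard_normal(n))
            pairs.append((f"pep{k}{i}", f"prot{k}"))
    values = np.column_stack(cols)
    eta = signal * factors[0]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    # guarantee both classes have >= 2 members
    y[:2] = 1
    y[2:4] = 0
    X = PeptideMatrix([f"S{j}" for j in range(n)], [p for p, _ in pairs], values)
    pheno = Phenotype(
        X.sample_ids, y, rng.uniform(34, 84, n), rng.integers(0, 2, n)
    )
    return X, Hierarchy.from_pairs(pairs), pheno


@pytest.fixture
def small_cohort():
    return make_cohort(n=40, seed=0)
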