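"""Domain containers for MRM-MS peptide panels.

Targeted proteomics by multiple-reaction-monitoring mass spectrometry (MRM-MS)
quantifies a preselected set of peptides per serum sample; each endogenous
("light") peptide is measured alongside a spiked stable-isotope ("heavy")
standard, and the log2 light:heavy ratio is the per-peptide abundance value.
Peptides are nested inside the proteins they were digested from, which gives
the data a two-level hierarchy: ``sample x peptide`` values plus a
``peptide -> protein`` map.

Three immutable containers carry this structure through the package:

``PeptideMatrix``
    samples x peptides matrix of log2(light/heavy) ratios.
``Hierarchy``
    the peptide -> protein nesting (K proteins with T_k peptides each).
``Phenotype``
    per-sample binary drug response plus age and sex covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DataError(ValueError):
    """An input table violates a structural or numerical requirement."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class PeptideMatrix:
    """Samples x peptides matrix of log2(light/heavy) peptide ratios.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row.
    peptide_ids
        Unique peptide identifiers, one per column.
    values
        Real matrix of shape ``(len(sample_ids), len(peptide_ids))``; every
        entry must be finite (missing measurements are rejected upstream).
    """

    sample_ids: tuple[str, ...]
    peptide_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "peptide_ids", tuple(str(p) for p in self.peptide_ids))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataError(f"values must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.sample_ids), len(self.peptide_ids)):
            raise DataError(
                f"values shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.peptide_ids)} peptides"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.peptide_ids, "peptide")
        bad = ~np.isfinite(values)
        if bad.any():
            j, k = np.argwhere(bad)[0]
            raise DataError(
                f"non-finite ratio for sample {self.sample_ids[j]!r}, "
                f"peptide {self.peptide_ids[k]!r}"
            )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.peptide_ids),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeptideMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(dtype=float))

    def subset_peptides(self, peptide_ids: Sequence[str]) -> "PeptideMatrix":
        """Column subset in the given order; unknown peptides raise."""
        index = {p: i for i, p in enumerate(self.peptide_ids)}
        try:
            cols = [index[p] for p in peptide_ids]
        except KeyError as err:
            raise DataError(f"unknown peptide identifier: {err.args[0]!r}") from None
        return PeptideMatrix(self.sample_ids, tuple(peptide_ids), self.values[:, cols])

    def subset_samples(self, rows: Sequence[int]) -> "PeptideMatrix":
        rows = list(rows)
        return PeptideMatrix(
            tuple(self.sample_ids[r] for r in rows), self.peptide_ids, self.values[rows, :]
        )


@dataclass(frozen=True)
class Hierarchy:
    """Peptide -> protein nesting.

    ``mapping`` assigns every peptide to exactly one protein; protein order is
    first-appearance order of the input pairs.  K is the number of proteins and
    T_k the peptide count of protein k.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        mapping = {str(p): str(g) for p, g in dict(self.mapping).items()}
        if not mapping:
            raise DataError("hierarchy is empty")
        object.__setattr__(self, "mapping", mapping)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Hierarchy":
        mapping: dict[str, str] = {}
        for pep, prot in pairs:
            pep, prot = str(pep), str(prot)
            if pep in mapping and mapping[pep] != prot:
                raise DataError(
                    f"peptide maps to multiple proteins: {pep!r} -> "
                    f"{mapping[pep]!r} and {prot!r}"
                )
            if pep in mapping:
                raise DataError(f"duplicate hierarchy row for peptide {pep!r}")
            mapping[pep] = prot
        return cls(mapping)

    @property
    def proteins(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for prot in self.mapping.values():
            seen.setdefault(prot, None)
        return tuple(seen)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def sizes(self) -> tuple[int, ...]:
        counts: dict[str, int] = {}
        for prot in self.mapping.values():
            counts[prot] = counts.get(prot, 0) + 1
        return tuple(counts[p] for p in self.proteins)

    def peptides_of(self, protein: str) -> tuple[str, ...]:
        return tuple(p for p, g in self.mapping.items() if g == protein)

    def groups_for(self, peptide_ids: Sequence[str]) -> tuple[tuple[str, ...], list[np.ndarray]]:
        """Column-index groups for a peptide column order.

        Returns the proteins that have at least one peptide among
        ``peptide_ids`` (in hierarchy order) and, per protein, the array of
        column indices of its peptides.  Peptides absent from the mapping are
        an error: a matrix used with a hierarchy must be fully covered.
        """
        for p in peptide_ids:
            if p not in self.mapping:
                raise DataError(f"peptide {p!r} missing from hierarchy")
        cols: dict[str, list[int]] = {}
        for i, p in enumerate(peptide_ids):
            cols.setdefault(self.mapping[p], []).append(i)
        proteins = tuple(g for g in self.proteins if g in cols)
        groups = [np.asarray(cols[g], dtype=np.intp) for g in proteins]
        return proteins, groups


@dataclass(frozen=True)
class Phenotype:
    """Per-sample binary drug response with age and sex covariates.

    ``response`` is 1 for a positive drug response and 0 for a negative one;
    ``sex`` is a 0/1 code whose label mapping is a configuration concern
    (the package default records 1 = male, 0 = female).
    """

    sample_ids: tuple[str, ...]
    response: np.ndarray
    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        response = np.asarray(self.response)
        age = np.asarray(self.age, dtype=float)
        sex = np.asarray(self.sex)
        for name, arr in (("response", response), ("age", age), ("sex", sex)):
            if arr.shape != (n,):
                raise DataError(f"{name} must have one entry per sample")
        if not np.isin(response, (0, 1)).all():
            bad = response[~np.isin(response, (0, 1))][0]
            raise DataError(f"response must be 0 or 1, got {bad!r}")
        if not np.isin(sex, (0, 1)).all():
            raise DataError("sex code must be 0 or 1")
        if not np.all(np.isfinite(age)) or not np.all(age > 0):
            raise DataError("age must be a positive number")
        response = response.astype(np.int64)
        sex = sex.astype(np.int64)
        for arr in (response, age, sex):
            arr.setflags(write=False)
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "sex", sex)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_positive(self) -> int:
        return int(self.response.sum())

    def aligned_to(self, sample_ids: Sequence[str]) -> "Phenotype":
        """Reorder rows to match ``sample_ids``; missing samples raise."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[str(s)] for s in sample_ids]
        except KeyError as err:
            raise DataError(f"sample {err.args[0]!r} missing from phenotype table") from None
        return Phenotype(
            tuple(sample_ids), self.response[rows], self.age[rows], self.sex[rows]
        )

    def subset(self, rows: Sequence[int]) -> "Phenotype":
        rows = list(rows)
        return Phenotype(
            tuple(self.sample_ids[r] for r in rows),
            self.response[rows],
            self.age[rows],
            self.sex[rows],
        )

    def covariate_matrix(self) -> np.ndarray:
        """n x 2 array of (age, sex) in sample order."""
        return np.column_stack([self.age, self.sex.astype(float)])
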