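"""Readers and writers for quantitation tables and model artifacts.

All tables are TSV by default (``sep=","`` for comma dialects); sample
alignment across files is always by sample identifier, never by row order.

Two quantitation dialects are supported:

wide
    first column ``sample_id``, remaining columns peptide identifiers, cells
    already log2(light/heavy) ratios.
long
    one row per (peptide, sample) measurement with columns
    ``peptide_id, protein_id, sample_id, light_area, heavy_area`` (a
    Skyline-style transition-results export collapsed to peak areas); the
    reader forms log2(light/heavy) per record and pivots to wide.  Column
    names can be remapped via ``column_map`` for export variants.

Fitted models persist as a single self-describing YAML document holding the
coefficients, ridge parameters, standardization statistics and iteration log;
``write_fit`` / ``read_fit`` round-trip losslessly.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import DataError, Hierarchy, PeptideMatrix, Phenotype
from .core import HisComFit, ModelConfig, Standardizer

LONG_COLUMNS = ("peptide_id", "protein_id", "sample_id", "light_area", "heavy_area")

_FIT_FORMAT = "hiscom-model"
_FIT_VERSION = 1


def _read_table(path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as err:
        raise DataError(f"cannot read table {path}: {err}") from None
    if df.empty:
        raise DataError(f"table {path} contains no rows")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise DataError(
            f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row} of {path}"
        )
    if out.isna().any():
        row = int(np.argmax(out.isna().to_numpy()))
        raise DataError(f"missing value in column {col!r}, row {row} of {path}")
    # re-parse through float(): pandas' fast path is not round-trip exact
    return np.array([float(x) for x in df[col]], dtype=float)


def read_quant_matrix(
    path,
    dialect: str = "wide",
    sep: str = "\t",
    column_map: Mapping[str, str] | None = None,
    drop_incomplete_samples: bool = False,
) -> PeptideMatrix:
    """Read a peptide quantitation table as a :class:`PeptideMatrix`.

    Parameters
    ----------
    dialect
        ``"wide"`` (samples x peptides of log2 ratios) or ``"long"``
        (per-measurement light/heavy areas, ratioed and pivoted here).
    column_map
        For the long dialect, maps canonical column names
        (:data:`LONG_COLUMNS`) to the names used in the file.
    drop_incomplete_samples
        Listwise-delete samples with any missing peptide value instead of
        rejecting the table.
    """
    if dialect == "wide":
        return _read_wide(path, sep, drop_incomplete_samples)
    if dialect == "long":
        return _read_long(path, sep, column_map, drop_incomplete_samples)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def _finish_wide(df: pd.DataFrame, path, drop_incomplete_samples: bool) -> PeptideMatrix:
    if df.isna().any().any():
        if drop_incomplete_samples:
            df = df.dropna(axis=0, how="any")
            if df.empty:
                raise DataError(f"all samples of {path} have missing peptide values")
        else:
            row = df.index[df.isna().any(axis=1)][0]
            col = df.columns[df.loc[row].isna()][0]
            raise DataError(
                f"missing ratio for sample {row!r}, peptide {col!r} in {path} "
                "(use drop_incomplete_samples to listwise-delete)"
            )
    return PeptideMatrix.from_frame(df)


def _read_wide(path, sep: str, drop_incomplete_samples: bool) -> PeptideMatrix:
    raw = _read_table(path, sep)
    sample_col = raw.columns[0]
    if raw[sample_col].duplicated().any():
        dup = raw[sample_col][raw[sample_col].duplicated()].iloc[0]
        raise DataError(f"duplicate sample identifier {dup!r} in {path}")
    values = {}
    for col in raw.columns[1:]:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = raw[sample_col][bad].iloc[0]
            raise DataError(
                f"non-numeric cell for sample {row!r}, peptide {col!r} in {path}"
            )
        values[col] = raw[col].map(lambda s: np.nan if pd.isna(s) else float(s))
    df = pd.DataFrame(values)
    df.index = pd.Index(raw[sample_col], name="sample_id")
    return _finish_wide(df, path, drop_incomplete_samples)


def _read_long(
    path, sep: str, column_map: Mapping[str, str] | None, drop_incomplete_samples: bool
) -> PeptideMatrix:
    raw = _read_table(path, sep)
    rename = {}
    for canon in LONG_COLUMNS:
        actual = (column_map or {}).get(canon, canon)
        if actual not in raw.columns:
            raise DataError(f"long table {path} lacks required column {actual!r}")
        rename[actual] = canon
    df = raw.rename(columns=rename)
    dup = df.duplicated(subset=["sample_id", "peptide_id"])
    if dup.any():
        r = df[dup].iloc[0]
        raise DataError(
            f"duplicate record for sample {r['sample_id']!r}, peptide {r['peptide_id']!r} in {path}"
        )
    light = _numeric(df, "light_area", path)
    heavy = _numeric(df, "heavy_area", path)
    for name, arr in (("light", light), ("heavy", heavy)):
        nonpos = arr <= 0
        if nonpos.any():
            i = int(np.argmax(nonpos))
            raise DataError(
                f"nonpositive {name} intensity ({arr[i]!r}) for peptide "
                f"{df['peptide_id'].iloc[i]!r}, sample {df['sample_id'].iloc[i]!r} in {path}"
            )
    df = df.assign(ratio=np.log2(light / heavy))
    sample_order = pd.unique(df["sample_id"])
    peptide_order = pd.unique(df["peptide_id"])
    wide = df.pivot(index="sample_id", columns="peptide_id", values="ratio")
    wide = wide.reindex(index=sample_order, columns=peptide_order)
    wide.index.name = "sample_id"
    return _finish_wide(wide, path, drop_incomplete_samples)


def hierarchy_from_long(path, sep: str = "\t", column_map: Mapping[str, str] | None = None) -> Hierarchy:
    """Extract the peptide -> protein map from a long quantitation table."""
    raw = _read_table(path, sep)
    pep = (column_map or {}).get("peptide_id", "peptide_id")
    prot = (column_map or {}).get("protein_id", "protein_id")
    for col in (pep, prot):
        if col not in raw.columns:
            raise DataError(f"long table {path} lacks required column {col!r}")
    pairs = raw[[pep, prot]].drop_duplicates()
    return Hierarchy.from_pairs(pairs.itertuples(index=False))


def write_quant_matrix(X: PeptideMatrix, path, sep: str = "\t") -> None:
    # %.17g keeps the write -> read round trip bit-exact for doubles
    X.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def read_hierarchy(path, sep: str = "\t") -> Hierarchy:
    """Read a two-column (peptide_id, protein_id) mapping table."""
    df = _read_table(path, sep)
    if df.shape[1] < 2:
        raise DataError(f"hierarchy table {path} needs two columns (peptide_id, protein_id)")
    return Hierarchy.from_pairs(df.iloc[:, :2].itertuples(index=False))


def write_hierarchy(hierarchy: Hierarchy, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"peptide_id": list(hierarchy.mapping), "protein_id": list(hierarchy.mapping.values())}
    ).to_csv(path, sep=sep, index=False)


def read_phenotype(path, sep: str = "\t") -> Phenotype:
    """Read a (sample_id, response, age, sex) phenotype table."""
    df = _read_table(path, sep)
    for col in ("sample_id", "response", "age", "sex"):
        if col not in df.columns:
            raise DataError(f"phenotype table {path} lacks required column {col!r}")
    response = _numeric(df, "response", path)
    if not np.isin(response, (0, 1)).all():
        i = int(np.argmax(~np.isin(response, (0, 1))))
        raise DataError(
            f"response must be 0 or 1; got {response[i]!r} for sample {df['sample_id'].iloc[i]!r}"
        )
    return Phenotype(
        tuple(df["sample_id"]),
        response.astype(int),
        _numeric(df, "age", path),
        _numeric(df, "sex", path).astype(int),
    )


def write_phenotype(pheno: Phenotype, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "sample_id": pheno.sample_ids,
            "response": pheno.response,
            "age": pheno.age,
            "sex": pheno.sex,
        }
    ).to_csv(path, sep=sep, index=False, float_format="%.17g")


_REQUIRED_FIT_KEYS = (
    "format",
    "version",
    "peptide_ids",
    "protein_ids",
    "pep_protein_ids",
    "w",
    "beta",
    "lambda_pep",
    "lambda_prot",
    "standardizer",
    "config",
    "objective_trace",
    "converged",
    "n_iter",
)


def write_fit(fit: HisComFit, path) -> None:
    """Persist a fitted model as a self-describing YAML artifact."""
    doc = {
        "format": _FIT_FORMAT,
        "version": _FIT_VERSION,
        "peptide_ids": list(fit.peptide_ids),
        "protein_ids": list(fit.protein_ids),
        "pep_protein_ids": list(fit.pep_protein_ids),
        "w": [float(x) for x in fit.w],
        "beta": [float(x) for x in fit.beta],
        "beta_age": None if fit.beta_age is None else float(fit.beta_age),
        "beta_sex": None if fit.beta_sex is None else float(fit.beta_sex),
        "lambda_pep": float(fit.config.lambda_pep),
        "lambda_prot": float(fit.config.lambda_prot),
        "standardizer": None
        if fit.standardizer is None
        else {
            "peptide_ids": list(fit.standardizer.peptide_ids),
            "mean": [float(x) for x in fit.standardizer.mean],
            "sd": [float(x) for x in fit.standardizer.sd],
        },
        "config": {
            "lambda_pep": float(fit.config.lambda_pep),
            "lambda_prot": float(fit.config.lambda_prot),
            "penalize_intercept": bool(fit.config.penalize_intercept),
            "penalize_covariates": bool(fit.config.penalize_covariates),
            "tol": float(fit.config.tol),
            "max_outer_iter": int(fit.config.max_outer_iter),
            "max_inner_iter": int(fit.config.max_inner_iter),
            "seed": fit.config.seed,
        },
        "objective_trace": [float(x) for x in fit.objective_trace],
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_fit(path) -> HisComFit:
    """Load a model artifact written by :func:`write_fit`."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as err:
        raise DataError(f"cannot read model file {path}: {err}") from None
    if not isinstance(doc, dict):
        raise DataError(f"model file {path} is not a key/value document")
    missing = [k for k in _REQUIRED_FIT_KEYS if k not in doc]
    if missing:
        raise DataError(f"incomplete model file {path}: missing {', '.join(missing)}")
    if doc["format"] != _FIT_FORMAT:
        raise DataError(f"model file {path} has unknown format {doc['format']!r}")
    cfg = doc["config"]
    config = ModelConfig(
        lambda_pep=cfg["lambda_pep"],
        lambda_prot=cfg["lambda_prot"],
        penalize_intercept=cfg["penalize_intercept"],
        penalize_covariates=cfg["penalize_covariates"],
        tol=cfg["tol"],
        max_outer_iter=cfg["max_outer_iter"],
        max_inner_iter=cfg["max_inner_iter"],
        seed=cfg.get("seed"),
    )
    std = None
    if doc["standardizer"] is not None:
        s = doc["standardizer"]
        std = Standardizer(
            tuple(s["peptide_ids"]),
            np.asarray(s["mean"], dtype=float),
            np.asarray(s["sd"], dtype=float),
        )
    return HisComFit(
        peptide_ids=tuple(doc["peptide_ids"]),
        protein_ids=tuple(doc["protein_ids"]),
        pep_protein_ids=tuple(doc["pep_protein_ids"]),
        w=np.asarray(doc["w"], dtype=float),
        beta=np.asarray(doc["beta"], dtype=float),
        beta_age=doc.get("beta_age"),
        beta_sex=doc.get("beta_sex"),
        standardizer=std,
        config=config,
        objective_trace=tuple(doc["objective_trace"]),
        converged=doc["converged"],
        n_iter=doc["n_iter"],
    )
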