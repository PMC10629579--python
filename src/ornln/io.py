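"""Labeled-matrix CSV/TSV input-output and parameter bundles.

The on-disk matrix dialect is UTF-8 CSV (or TSV): first row = sample/column
labels, first column = channel/row labels, '.' decimal separator, no
thousands separators.  Round trips are loss-free to 1e-12 (values are
written with 17 significant digits).

A *bundle* is a directory with labeled CSVs for W, M and optionally Y, Z,
plus ``metadata.json`` recording rho, K, mode, seeds, tolerances, package
version and an input checksum, so a fitted circuit can be reloaded and
re-run without re-specifying its parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ActivityEnsemble, CircuitParams, CircuitResponse, InputError

__all__ = [
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_ensemble",
    "write_ensemble",
    "save_bundle",
    "load_bundle",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise InputError(f"unknown dialect {dialect!r} (use 'csv' or 'tsv')")


def read_labeled_matrix(path, dialect: str = "csv") -> pd.DataFrame:
    """Read a labeled matrix; errors name the offending row/column."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    except pd.errors.ParserError as e:
        raise InputError(f"{path}: malformed file: {e}") from e
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise InputError(f"{path}: duplicate row label(s) {dup}")
    if df.columns.has_duplicates:
        dup = [c for c in df.columns if list(df.columns).count(c) > 1]
        raise InputError(f"{path}: duplicate column label(s) {sorted(set(dup))}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise InputError(f"{path}: non-numeric cell at row {bad[0]!r}, column {col!r}")
        df[col] = vals
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise InputError(f"{path}: missing value in row {row!r}")
    return df


def write_labeled_matrix(
    matrix: np.ndarray, path, row_labels, col_labels, dialect: str = "csv"
) -> None:
    df = pd.DataFrame(np.asarray(matrix, float), index=list(row_labels), columns=list(col_labels))
    df.to_csv(Path(path), sep=_sep(dialect), float_format=_FLOAT_FMT)


def read_ensemble(path, dialect: str = "csv", nonneg: bool = False) -> ActivityEnsemble:
    df = read_labeled_matrix(path, dialect)
    return ActivityEnsemble(
        df.to_numpy(float),
        channel_labels=[str(i) for i in df.index],
        sample_labels=[str(c) for c in df.columns],
        nonneg=nonneg,
    )


def write_ensemble(ensemble: ActivityEnsemble, path, dialect: str = "csv") -> None:
    labels = [
        "|".join(l) if isinstance(l, tuple) else str(l) for l in ensemble.sample_labels
    ]
    write_labeled_matrix(ensemble.X, path, ensemble.channel_labels, labels, dialect)


def _checksum(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X, dtype=float).tobytes()).hexdigest()


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("ornln")
    except Exception:
        return "unknown"


def save_bundle(
    params: CircuitParams,
    response: CircuitResponse | None,
    directory,
    input_ensemble: ActivityEnsemble | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Persist a fitted circuit to a directory of labeled CSVs + metadata."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    D, K = params.D, params.K
    ch = input_ensemble.channel_labels if input_ensemble is not None else [f"ch{i}" for i in range(D)]
    ln = [f"LN{k}" for k in range(K)]
    write_labeled_matrix(params.W, d / "W.csv", ch, ln)
    write_labeled_matrix(params.M, d / "M.csv", ln, ln)
    meta = {
        "rho": params.rho,
        "K": K,
        "D": D,
        "mode": params.constraint,
        "package_version": _package_version(),
    }
    if response is not None:
        sl = (
            ["|".join(l) if isinstance(l, tuple) else str(l) for l in input_ensemble.sample_labels]
            if input_ensemble is not None
            else [f"s{t}" for t in range(response.Y.shape[1])]
        )
        write_labeled_matrix(response.Y, d / "Y.csv", ch, sl)
        write_labeled_matrix(response.Z, d / "Z.csv", ln, sl)
        meta["n_samples"] = response.Y.shape[1]
        meta["all_converged"] = bool(response.all_converged)
    if input_ensemble is not None:
        meta["input_checksum"] = _checksum(input_ensemble.X)
    if extra_meta:
        meta.update(extra_meta)
    (d / "metadata.json").write_text(json.dumps(meta, indent=2, default=float))
    return d


def load_bundle(directory, input_ensemble: ActivityEnsemble | None = None):
    """Load a bundle back into (CircuitParams, metadata dict).

    A checksum mismatch against ``input_ensemble`` logs a warning; a missing
    member is an error.
    """
    d = Path(directory)
    meta_path = d / "metadata.json"
    if not meta_path.exists():
        raise InputError(f"{d}: missing metadata.json")
    meta = json.loads(meta_path.read_text())
    for member in ("W.csv", "M.csv"):
        if not (d / member).exists():
            raise InputError(f"{d}: missing bundle member {member}")
    W = read_labeled_matrix(d / "W.csv").to_numpy(float)
    M = read_labeled_matrix(d / "M.csv").to_numpy(float)
    if input_ensemble is not None and "input_checksum" in meta:
        if _checksum(input_ensemble.X) != meta["input_checksum"]:
            logger.warning("%s: input checksum mismatch with provided ensemble", d)
    params = CircuitParams(W=W, M=M, rho=float(meta["rho"]), constraint=meta.get("mode", "linear"))
    return params, meta
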