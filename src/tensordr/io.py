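"""Readers and writers for the delimited matrix interchange format.

Matrices travel as tab-delimited text with an identifier header row and
an identifier first column.  Association files are diseases x drugs;
similarity files are square with matching row/column identifiers.
Values are written with 17 significant digits so a write/read round
trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import AssociationMatrix, SimilarityMatrix

__all__ = ["read_matrix", "write_matrix", "MatrixFormatError"]

_ASYM_TOL = 1e-8


class MatrixFormatError(ValueError):
    """A delimited matrix file violates the format contract."""


def _load_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MatrixFormatError(f"matrix file not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise MatrixFormatError(f"{path}: duplicate column identifiers {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # malformed delimiter/quoting
        raise MatrixFormatError(f"{path}: cannot parse delimited matrix: {exc}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise MatrixFormatError(f"{path}: duplicate row identifiers {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise MatrixFormatError(f"{path}: duplicate column identifiers {dupes}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise MatrixFormatError(
                f"{path}: non-numeric value at row '{row}', column '{col}'"
            )
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().values)[0]
        raise MatrixFormatError(
            f"{path}: missing value at row '{df.index[i]}', column '{df.columns[j]}'"
        )
    return df


def read_matrix(
    path: str | Path, kind: str = "association"
) -> AssociationMatrix | SimilarityMatrix:
    """Load and validate a delimited matrix.

    ``kind``: ``association`` (strictly binary), ``association_real``
    (values in [0, 1], e.g. after WKNN densification) or ``similarity``
    (square, unit diagonal; asymmetry up to 1e-8 is symmetrised by
    averaging with the transpose, larger asymmetry is rejected).
    """
    if kind not in ("association", "association_real", "similarity"):
        raise ValueError(f"unknown matrix kind '{kind}'")
    df = _load_frame(path)
    values = df.to_numpy(dtype=float)
    if kind == "similarity":
        if values.shape[0] != values.shape[1]:
            raise MatrixFormatError(f"{path}: similarity matrix must be square")
        if list(df.index) != list(df.columns):
            raise MatrixFormatError(
                f"{path}: similarity row and column identifiers differ"
            )
        asym = float(np.max(np.abs(values - values.T), initial=0.0))
        if asym > _ASYM_TOL:
            i, j = np.unravel_index(
                np.argmax(np.abs(values - values.T)), values.shape
            )
            raise MatrixFormatError(
                f"{path}: grossly asymmetric ({asym:.2e}) at row "
                f"'{df.index[i]}', column '{df.columns[j]}'"
            )
        values = (values + values.T) / 2.0
        if np.max(np.abs(np.diag(values) - 1.0)) > _ASYM_TOL:
            i = int(np.argmax(np.abs(np.diag(values) - 1.0)))
            raise MatrixFormatError(
                f"{path}: diagonal entry at '{df.index[i]}' is not 1"
            )
        np.fill_diagonal(values, 1.0)
        _check_range(values, path, df)
        return SimilarityMatrix(values, tuple(map(str, df.index)))
    _check_range(values, path, df)
    if kind == "association" and not np.all((values == 0) | (values == 1)):
        i, j = np.argwhere((values != 0) & (values != 1))[0]
        raise MatrixFormatError(
            f"{path}: association value {values[i, j]} at row '{df.index[i]}', "
            f"column '{df.columns[j]}' is not binary"
        )
    return AssociationMatrix(
        values, tuple(map(str, df.index)), tuple(map(str, df.columns))
    )


def _check_range(values: np.ndarray, path, df) -> None:
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixFormatError(
            f"{path}: value {values[i, j]} at row '{df.index[i]}', column "
            f"'{df.columns[j]}' is outside [0, 1]"
        )


def write_matrix(
    obj: AssociationMatrix | SimilarityMatrix | "PredictionMatrix",
    path: str | Path,
) -> None:
    """Write a matrix as tab-delimited text (17 significant digits)."""
    if isinstance(obj, SimilarityMatrix):
        values, rows, cols = obj.values, obj.ids, obj.ids
    elif hasattr(obj, "disease_ids") and hasattr(obj, "drug_ids"):
        values = obj.scores if hasattr(obj, "scores") else obj.values
        rows, cols = obj.disease_ids, obj.drug_ids
    else:
        raise TypeError(f"cannot serialise object of type {type(obj).__name__}")
    df = pd.DataFrame(values, index=list(rows), columns=list(cols))
    df.to_csv(path, sep="\t", float_format="%.17g")
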