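"""File formats: pedigree text files, dense relationship matrices as TSV,
and tidy result tables as TSV or JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelationshipSet

__all__ = [
    "read_pedigree",
    "read_matrix",
    "write_matrix",
    "read_relationships",
    "write_results",
    "read_results",
]

_HEADER_TOKENS = {"animal", "animal_id", "id", "progeny", "offspring"}


def read_pedigree(path: Union[str, Path]) -> Pedigree:
    """Three whitespace/tab-separated columns animal/sire/dam; '0' or empty
    marks an unknown parent; a header line is detected and skipped."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or line.lstrip().startswith("#"):
                continue
            if lineno == 1 and fields[0].lower() in _HEADER_TOKENS:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            records.append(tuple(fields[:3]))
    if not records:
        raise ValueError(f"{path}: empty pedigree")
    return Pedigree(records)


def read_matrix(path: Union[str, Path]) -> tuple[np.ndarray, list[str]]:
    """Dense matrix in TSV with an id header row and id first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"{path}: row and column ids differ")
    return df.to_numpy(dtype=float), ids


def write_matrix(M: np.ndarray, ids, path: Union[str, Path]) -> None:
    pd.DataFrame(np.asarray(M), index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_relationships(
    a_path: Union[str, Path], d_path: Optional[Union[str, Path]] = None
) -> RelationshipSet:
    """A (and optionally D) from TSV files, with structural validation.

    Without a D file, the non-inbred both-parents-known convention D = I/2
    is assumed (sufficient for all methods except QTDT on inbred data).
    """
    A, ids = read_matrix(a_path)
    if d_path is not None:
        D, d_ids = read_matrix(d_path)
        if d_ids != ids:
            raise ValueError("A and D files index different animals")
    else:
        D = 0.5 * np.eye(A.shape[0])
    return RelationshipSet(A, D, ids)


def _round6(v):
    if isinstance(v, float):
        return float(f"{v:.6g}")
    return v


def write_results(table: pd.DataFrame, path: Union[str, Path], fmt: str = "tsv") -> None:
    """Deterministic column order, floats at 6 significant digits; the TSV
    and JSON encodings carry identical numbers."""
    df = table.copy()
    for c in df.columns:
        if df[c].dtype.kind == "f":
            df[c] = df[c].map(lambda v: _round6(v) if pd.notna(v) else v)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, allow_nan=True)
            fh.write("\n")
    else:
        raise ValueError("format must be 'tsv' or 'json'")


def read_results(path: Union[str, Path], fmt: str = "tsv") -> pd.DataFrame:
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
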