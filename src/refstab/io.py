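"""Readers and writers for the tabular formats the pipeline consumes.

Inputs are plain TSV/CSV: a long (tidy) Cq table, a genes-in-rows count
matrix plus a sample metadata table.  Outputs are TSV result tables with a
stable column order and six-significant-digit floats, so a written table
re-read at that precision reproduces its values exactly.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .aggregate import ComprehensiveRanking
from .datamodel import (
    CountMatrix,
    CqTable,
    FormatError,
    IntegrityError,
    ParseError,
)
from .expression import ExpressionResult
from .screen import ScreenResult
from .stability import StabilityResult

__all__ = [
    "read_cq_table",
    "read_wide_cq_table",
    "write_cq_table",
    "read_count_matrix",
    "write_count_matrix",
    "write_result_table",
    "result_to_frame",
    "write_json_summary",
]

FLOAT_FORMAT = "%.6g"


def _sniff_sep(path: str | Path, dialect: str | None) -> str:
    if dialect:
        return {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    sample = Path(path).read_text().splitlines()[0] if Path(path).exists() else ""
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_cq_table(path: str | Path, dialect: str | None = None) -> CqTable:
    """Read a long-format Cq table.

    Required columns (case-insensitive): gene, condition, replicate, cq; a
    sample column is optional and synthesised as ``condition_replicate``
    when absent.  "NA", "NaN" or empty Cq cells become missing values;
    anything else non-numeric is a parse error naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = _sniff_sep(path, dialect)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for required in ("gene", "condition", "replicate", "cq"):
        if required not in frame.columns:
            raise FormatError(f"missing column {required!r} in {path.name}")
    cq = pd.Series(np.nan, index=frame.index)
    for i, raw in frame["cq"].items():
        text = raw.strip()
        if text in ("", "NA", "NaN", "nan", "na"):
            continue
        try:
            cq[i] = float(text)
        except ValueError:
            raise ParseError(
                f"non-numeric Cq {raw!r} at data row {i + 2} of {path.name}"
            ) from None
    frame = frame.assign(cq=cq)
    try:
        frame["replicate"] = frame["replicate"].astype(int)
    except ValueError as exc:
        raise ParseError(f"non-integer replicate index in {path.name}: {exc}") from None
    return CqTable.from_long(frame)


def read_wide_cq_table(
    path: str | Path, meta_path: str | Path, dialect: str | None = None
) -> CqTable:
    """Convenience reader for a genes-in-rows Cq matrix plus metadata.

    Converts to long form and defers to the same validation as
    :func:`read_cq_table`.
    """
    sep = _sniff_sep(path, dialect)
    wide = pd.read_csv(path, sep=sep, index_col=0)
    meta = _read_meta(meta_path, dialect)
    long = (
        wide.rename_axis(index="gene", columns="sample")
        .stack(future_stack=True)
        .rename("cq")
        .reset_index()
    )
    long["condition"] = long["sample"].map(meta["condition"])
    long["replicate"] = long["sample"].map(meta["replicate"])
    if long["condition"].isna().any():
        unknown = sorted(set(long.loc[long["condition"].isna(), "sample"]))
        raise IntegrityError(f"samples without metadata: {unknown}")
    return CqTable.from_long(long)


def write_cq_table(table: CqTable, path: str | Path) -> None:
    long = table.to_long()
    long["cq"] = long["cq"].map(
        lambda v: "" if pd.isna(v) else FLOAT_FORMAT % v
    )
    long.to_csv(path, sep="\t", index=False)


def _read_meta(meta_path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    sep = _sniff_sep(meta_path, dialect)
    meta = pd.read_csv(meta_path, sep=sep, dtype=str)
    meta.columns = [c.strip().lower() for c in meta.columns]
    for required in ("sample", "condition", "replicate"):
        if required not in meta.columns:
            raise FormatError(f"metadata is missing column {required!r}")
    if meta["sample"].duplicated().any():
        raise IntegrityError("duplicate sample in metadata")
    meta = meta.set_index("sample")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def read_count_matrix(
    path: str | Path, meta_path: str | Path, dialect: str | None = None
) -> CountMatrix:
    """Read a genes-in-rows count matrix and its sample metadata.

    The first header token of the matrix file must be ``gene``.  Counts
    must be non-negative integers; each matrix sample needs a metadata row.
    """
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    raw = pd.read_csv(path, sep=sep)
    first = raw.columns[0].strip().lower()
    if first != "gene":
        raise FormatError(
            f"count matrix must have 'gene' as first header token, got {raw.columns[0]!r}"
        )
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "gene"
    arr = raw.apply(pd.to_numeric, errors="coerce")
    if arr.isna().any().any():
        gene = arr.index[arr.isna().any(axis=1)][0]
        raise ParseError(f"non-numeric count for gene {gene!r}")
    if (arr.to_numpy() != np.round(arr.to_numpy())).any() or (arr.to_numpy() < 0).any():
        raise ParseError("counts must be non-negative integers")
    meta = _read_meta(meta_path, dialect)
    unknown = [s for s in arr.columns if s not in meta.index]
    if unknown:
        raise IntegrityError(f"samples in matrix but not in metadata: {unknown}")
    return CountMatrix(arr.astype(np.int64), meta.loc[list(arr.columns)])


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, meta_path: str | Path
) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    meta = matrix.meta.copy()
    meta.index.name = "sample"
    meta.to_csv(meta_path, sep="\t")


def result_to_frame(result: Any) -> pd.DataFrame:
    """Canonical tabular form (stable column order) of any result object."""
    if isinstance(result, StabilityResult):
        out = result.ordered().reset_index()
        return out
    if isinstance(result, ComprehensiveRanking):
        return result.table.reset_index()
    if isinstance(result, ScreenResult):
        out = result.table.reset_index()
        return out
    if isinstance(result, ExpressionResult):
        return result.summary.reset_index()
    if isinstance(result, pd.DataFrame):
        return result.reset_index() if result.index.name else result
    raise FormatError(f"cannot serialise result of type {type(result).__name__}")


def write_result_table(result: Any, path: str | Path) -> None:
    """Write any result as TSV with six-significant-digit floats."""
    frame = result_to_frame(result)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_json_summary(summary: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.ndarray, pd.Series)):
            return list(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default) + "\n")
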