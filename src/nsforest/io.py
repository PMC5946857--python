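"""Readers and writers for the tabular and sparse formats the tool touches.

Dense matrices are TSV/CSV with a header row of cell ids and a first column
of gene ids.  Sparse matrices are MatrixMarket coordinate files with sidecar
``genes.txt`` / ``barcodes.txt`` id lists (one per line) in the same
directory.  Cluster assignments are two-column tables.  Marker reports are
TSV or lossless JSON.
"""
from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import ClusterAssignment, ExpressionMatrix, MarkerSet, ValidationError

__all__ = [
    "ParseError",
    "load_expression_matrix",
    "load_cluster_assignment",
    "write_marker_report",
    "read_marker_report",
    "atomic_write_text",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


_SEPS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx"):
        return suffix
    if suffix == "txt":
        return "tsv"
    raise ParseError(f"cannot infer format from suffix {path.suffix!r}; pass format=")


def load_expression_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (dense) or MatrixMarket (sparse).

    Orientation is genes-as-rows; ``transpose=True`` accepts cells-as-rows
    input and flips it on load.  Sparse input is densified (explicit zeros
    preserved).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt in _SEPS:
        try:
            df = pd.read_csv(path, sep=_SEPS[fmt], index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
            raise ParseError(f"malformed {fmt} file {path}: {exc}") from exc
        non_numeric = df.columns[
            [not np.issubdtype(dt, np.number) for dt in df.dtypes]
        ]
        if len(non_numeric):
            for col in non_numeric:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
                if len(bad):
                    # +2: header line plus 1-based numbering
                    line = df.index.get_loc(bad.index[0]) + 2
                    raise ParseError(
                        f"{path}, line {line}: non-numeric value "
                        f"{bad[col].iloc[0]!r} in column {col!r}"
                    )
            df = df.astype(float)
        genes, cells = list(map(str, df.index)), list(map(str, df.columns))
        values = df.to_numpy(dtype=float)
    elif fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ParseError(f"malformed MatrixMarket file {path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        genes = _read_id_list(path.parent / "genes.txt")
        cells = _read_id_list(path.parent / "barcodes.txt")
    else:
        raise ParseError(f"unsupported format {fmt!r}")
    if transpose:
        genes, cells = cells, genes
        values = values.T
    return ExpressionMatrix(genes, cells, values)


def _read_id_list(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(
            f"MatrixMarket sidecar id file missing: {path} "
            "(expected genes.txt and barcodes.txt alongside the .mtx)"
        )
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_cluster_assignment(
    path: str | os.PathLike, matrix: ExpressionMatrix
) -> ClusterAssignment:
    """Read a two-column (cell_id, cluster label) table; header optional."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    mapping: dict[str, str] = {}
    known = set(matrix.cell_ids)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise ParseError(
                    f"{path}, line {lineno}: expected 2 columns, got {len(parts)}"
                )
            cell, label = (p.strip() for p in parts)
            if lineno == 1 and cell not in known:
                continue  # header row
            if cell in mapping:
                raise ParseError(f"{path}, line {lineno}: duplicate cell id {cell!r}")
            mapping[cell] = label
    return ClusterAssignment.from_mapping(mapping, matrix)


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_marker_report(
    marker_sets: Sequence[MarkerSet],
    path: str | os.PathLike,
    format: str = "tsv",
) -> None:
    """Write marker sets as a per-cluster TSV table or lossless JSON."""
    if not marker_sets:
        raise ValidationError("marker report requires a non-empty list")
    path = Path(path)
    if format == "json":
        atomic_write_text(
            path,
            json.dumps([m.to_dict() for m in marker_sets], indent=2) + "\n",
        )
    elif format == "tsv":
        lines = ["cluster\tpositive_markers\tnegative_markers\tscore\tthresholds"]
        for m in marker_sets:
            thr = ";".join(f"{g}={float(m.thresholds[g])}" for g in m.markers)
            lines.append(
                f"{m.target_cluster}\t{';'.join(m.positive_markers)}\t"
                f"{';'.join(m.negative_markers)}\t{float(m.score)}\t{thr}"
            )
        atomic_write_text(path, "\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported marker report format {format!r}")


def read_marker_report(path: str | os.PathLike) -> list[MarkerSet]:
    """Read back a JSON marker report written by :func:`write_marker_report`."""
    with open(path) as fh:
        data = json.load(fh)
    return [MarkerSet.from_dict(d) for d in data]
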