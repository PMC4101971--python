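"""Delimited-text I/O and pixelized matrix rendering.

Feature tables, dissimilarity matrices and label files are plain comma- or
tab-delimited text with an optional header row; identifiers are preserved
end to end so orderings and partitions refer to input ids, not positions.
Matrices are written at full precision (repr round-trip).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .neighborhood import DissimilarityMatrix, FeatureTable
from .partition import Partition
from .seriation import OrderingResult

__all__ = [
    "read_table",
    "write_matrix",
    "write_features",
    "write_labels",
    "read_labels",
    "write_ordering",
    "render_matrix",
]

_ASYM_TOL = 1e-9


def _sniff_sep(path) -> str:
    first = Path(path).open().readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def _read_frame(path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, skip_blank_lines=True)
    if df.empty:
        raise ValueError(f"{path}: empty input")
    return df


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def read_table(path, kind: str = "features"):
    """Read a delimited text file into a typed object.

    ``kind="features"`` → FeatureTable (optional header column of row ids),
    ``kind="dissimilarity"`` → DissimilarityMatrix (symmetry enforced to
    1e-9), ``kind="labels"`` → dict id → label.
    """
    if kind == "labels":
        return read_labels(path)
    df = _read_frame(path)
    has_header = not df.iloc[0].map(_is_number).all()
    ids: list[str] = []
    if has_header:
        header = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
        # a leading id column is flagged by its header cell or non-numeric cells
        if header[0].lower() in ("id", "") or not df.iloc[:, 0].map(_is_number).all():
            ids = [str(v) for v in df.iloc[:, 0]]
            df = df.iloc[:, 1:]
        else:
            ids = header if kind == "dissimilarity" else []
    elif not df.iloc[:, 0].map(_is_number).all():
        ids = [str(v) for v in df.iloc[:, 0]]
        df = df.iloc[:, 1:]
    bad = ~df.map(_is_number)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at row {i + 1}, column {j + 1}"
        )
    values = df.to_numpy(dtype=float)
    if kind == "features":
        return FeatureTable(values=values, row_ids=ids)
    if kind == "dissimilarity":
        asym = np.abs(values - values.T)
        if asym.max(initial=0.0) > _ASYM_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"{path}: asymmetric dissimilarity at ({i + 1},{j + 1}): "
                f"{values[i, j]!r} != {values[j, i]!r}"
            )
        return DissimilarityMatrix(d=(values + values.T) / 2, ids=ids)
    raise ValueError(f"unknown table kind {kind!r}")


def write_matrix(M: np.ndarray, path, ids: list[str] | None = None, sep: str = "\t") -> None:
    """Write a matrix as delimited text at full precision."""
    M = np.asarray(M)
    with Path(path).open("w") as fh:
        if ids:
            fh.write(sep.join(str(i) for i in ids) + "\n")
        for row in M:
            fh.write(sep.join(repr(float(v)) if isinstance(v, (float, np.floating))
                              else str(int(v)) for v in row) + "\n")


def write_features(table: FeatureTable, path, sep: str = "\t") -> None:
    df = pd.DataFrame(table.values, index=pd.Index(table.row_ids, name="id"),
                      columns=[f"f{j + 1}" for j in range(table.p)])
    df.to_csv(path, sep=sep)


def write_labels(labels: dict, path, sep: str = "\t") -> None:
    """Two-column text: id, cluster-or-OUSTED."""
    with Path(path).open("w") as fh:
        for rid, lab in labels.items():
            fh.write(f"{rid}{sep}{lab}\n")


def read_labels(path) -> dict:
    out = {}
    sep = _sniff_sep(path)
    for line in Path(path).open():
        line = line.rstrip("\n")
        if not line:
            continue
        rid, lab = line.split(sep)[:2]
        out[rid] = int(lab) if _is_number(lab) and float(lab) == int(float(lab)) else lab
    return out


def write_ordering(result: OrderingResult, ids: list[str], path) -> None:
    """One identifier per line in seriated order; ousted ids flagged."""
    with Path(path).open("w") as fh:
        for col in result.permutation.order:
            fh.write(f"{ids[col]}\n")
        for col in result.permutation.ousted:
            fh.write(f"{ids[col]}\tOUSTED\n")


def render_matrix(M: np.ndarray, path) -> None:
    """Pixelize a matrix: one pixel per cell, black = 1 / high.

    Binary matrices come out pure black/white; real-valued matrices are
    mapped to grayscale by rank so the block structure survives outliers.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("render_matrix expects a non-empty 2-d matrix")
    uniq = np.unique(M)
    if set(uniq.tolist()) <= {0.0, 1.0}:
        gray = (1.0 - M) * 255.0
    elif uniq.size == 1:
        gray = np.full_like(M, 128.0)
    else:
        ranks = np.argsort(np.argsort(M, axis=None)).reshape(M.shape)
        gray = 255.0 * (1.0 - ranks / (M.size - 1))
    img = Image.fromarray(gray.astype(np.uint8), mode="L")
    img.save(Path(path))
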