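"""Core matrix/label containers and plain-text I/O.

The canonical in-memory orientation is cells x features (rows are cells);
every reader converts to it and every writer converts back to the on-disk
convention of the format (10x-style MTX directories store features x cells).
Gzip-compressed inputs are accepted transparently by extension sniffing.
"""

from __future__ import annotations

import gzip
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

if TYPE_CHECKING:  # pragma: no cover
    from .gating_engine import PurityCall

__all__ = [
    "FeatureMatrix",
    "CellLabels",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_dense",
    "write_dense",
    "read_cell_labels",
    "write_cell_labels",
    "write_labels",
    "read_labels",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        series = pd.Series(ids)
        dups = series[series.duplicated()].unique()
        raise ValueError(f"duplicate {what}: {list(dups[:5])!r}")


@dataclass
class FeatureMatrix:
    """A non-negative cells x features matrix with string identifiers.

    ``values`` holds counts (RNA/ADT) or activity scores (ATAC-derived
    gene activities); it may be dense or any scipy sparse format and is
    normalised to CSR. ``modality_tag`` is a free string ("rna", "adt",
    "atac-activity", ...) consulted only where a modality changes a
    default (e.g. ADT panels skip highly-variable-feature selection).
    """

    values: sp.csr_matrix
    feature_ids: np.ndarray
    cell_ids: np.ndarray
    modality_tag: str = "rna"

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsr()
        self.feature_ids = np.asarray(
            [str(f).strip() for f in self.feature_ids], dtype=object
        )
        self.cell_ids = np.asarray(
            [str(c).strip() for c in self.cell_ids], dtype=object
        )
        n_cells, n_features = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_features != len(self.feature_ids):
            raise ValueError(
                f"matrix has {n_features} columns but "
                f"{len(self.feature_ids)} feature ids"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.cell_ids, "cell ids")
        data = self.values.data
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("matrix contains non-finite values")
        if data.size and data.min() < 0:
            raise ValueError("matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "FeatureMatrix":
        """Row-subset preserving feature space and modality."""
        index = np.asarray(index)
        return FeatureMatrix(
            values=self.values[index],
            feature_ids=self.feature_ids,
            cell_ids=self.cell_ids[index],
            modality_tag=self.modality_tag,
        )

    def feature_index(self) -> dict:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class CellLabels:
    """Per-cell categorical labels (ground truth for evaluation)."""

    cell_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray([str(c) for c in self.cell_ids], dtype=object)
        self.labels = np.asarray([str(l) for l in self.labels], dtype=object)
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("one label per cell id required")
        _check_unique(self.cell_ids, "cell ids")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_one(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / (stem + suffix)
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"none of {list(stems)} (optionally .gz) found in {directory}"
    )


def _read_id_column(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].astype(str).str.strip().to_numpy(dtype=object)


def read_mtx_dir(path: os.PathLike | str) -> FeatureMatrix:
    """Read a 10x-style directory (matrix.mtx + features.tsv + barcodes.tsv).

    The on-disk matrix is features x cells and is transposed to the
    canonical cells x features orientation. Values are preserved exactly.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    mtx_path = _find_one(directory, ["matrix.mtx"])
    feat_path = _find_one(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find_one(directory, ["barcodes.tsv"])
    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = mmread(fh)
    features = _read_id_column(feat_path)
    barcodes = _read_id_column(bc_path)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"{mtx_path} declares shape {mat.shape} but features.tsv has "
            f"{len(features)} rows and barcodes.tsv has {len(barcodes)}"
        )
    return FeatureMatrix(
        values=sp.csr_matrix(mat.T),
        feature_ids=features,
        cell_ids=barcodes,
    )


def write_mtx_dir(matrix: FeatureMatrix, path: os.PathLike | str) -> None:
    """Write a FeatureMatrix as an uncompressed 10x-style MTX directory."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    on_disk = sp.coo_matrix(matrix.values.T)
    if np.issubdtype(on_disk.dtype, np.integer):
        mmwrite(str(directory / "matrix.mtx"), on_disk, field="integer")
    else:
        mmwrite(str(directory / "matrix.mtx"), on_disk, precision=17)
    pd.Series(matrix.feature_ids).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def _sep_for(path: Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    return "," if name.endswith(".csv") else "\t"


def read_dense(
    path: os.PathLike | str,
    orientation: str = "cells",
    modality_tag: str = "rna",
) -> FeatureMatrix:
    """Read a dense CSV/TSV with one id column and a header row.

    ``orientation`` declares what the file's rows are: "cells" or
    "features". The result is always cells x features.
    """
    path = Path(path)
    if orientation not in ("cells", "features"):
        raise ValueError("orientation must be 'cells' or 'features'")
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[row, col]!r} at row "
            f"{df.index[row]!r}, column {df.columns[col]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        raise ValueError(f"missing values in {path}")
    values = numeric.to_numpy(dtype=float)
    row_ids = df.index.astype(str).to_numpy(dtype=object)
    col_ids = df.columns.astype(str).to_numpy(dtype=object)
    if orientation == "features":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return FeatureMatrix(
        values=sp.csr_matrix(values),
        feature_ids=col_ids,
        cell_ids=row_ids,
        modality_tag=modality_tag,
    )


def write_dense(
    matrix: FeatureMatrix,
    path: os.PathLike | str,
    orientation: str = "cells",
) -> None:
    path = Path(path)
    if orientation not in ("cells", "features"):
        raise ValueError("orientation must be 'cells' or 'features'")
    df = pd.DataFrame(
        matrix.to_dense(), index=matrix.cell_ids, columns=matrix.feature_ids
    )
    if orientation == "features":
        df = df.T
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_cell_labels(path: os.PathLike | str) -> CellLabels:
    """Read a two-column TSV (cell_id, label) with a header row."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"expected two columns (cell_id, label) in {path}")
    return CellLabels(
        cell_ids=df.iloc[:, 0].to_numpy(dtype=object),
        labels=df.iloc[:, 1].to_numpy(dtype=object),
    )


def write_cell_labels(labels: CellLabels, path: os.PathLike | str) -> None:
    pd.DataFrame({"cell_id": labels.cell_ids, "label": labels.labels}).to_csv(
        Path(path), sep="\t", index=False
    )


def write_labels(calls: "PurityCall", path: os.PathLike | str) -> None:
    """Serialize a PurityCall as TSV.

    Columns: cell_id, one boolean column per gating level (level1..levelN,
    written as "True"/"False"), and final ("Pure"/"Impure"). Row order is
    the input cell order.
    """
    n_levels = calls.per_level.shape[1]
    data = {"cell_id": calls.cell_ids}
    for j in range(n_levels):
        data[f"level{j + 1}"] = calls.per_level[:, j]
    data["final"] = calls.final
    pd.DataFrame(data).to_csv(Path(path), sep="\t", index=False)


def read_labels(path: os.PathLike | str) -> "PurityCall":
    """Read back a TSV written by :func:`write_labels`."""
    from .gating_engine import PurityCall

    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    level_cols = [c for c in df.columns if c.startswith("level")]
    per_level = (
        df[level_cols].apply(lambda c: c == "True").to_numpy(dtype=bool)
        if len(df)
        else np.zeros((0, len(level_cols)), dtype=bool)
    )
    return PurityCall(
        cell_ids=df["cell_id"].to_numpy(dtype=object)
        if len(df)
        else np.array([], dtype=object),
        per_level=per_level,
        final=df["final"].to_numpy(dtype=object)
        if len(df)
        else np.array([], dtype=object),
    )
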