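"""Reading and writing single-cell count matrices.

Two on-disk formats are supported: the 10x CellRanger MTX directory
(``matrix.mtx[.gz]`` + ``barcodes.tsv[.gz]`` + ``features.tsv[.gz]``,
genes as MatrixMarket rows) and a dense TSV with gene rows, cell
columns and a header row of barcodes.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InvalidMatrixError

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_10x",
    "write_10x",
    "read_dense",
    "write_dense",
]


@dataclass
class NormalizedMatrix:
    """Real-valued genes x cells matrix produced by normalization."""

    gene_ids: np.ndarray
    barcodes: np.ndarray
    matrix: sp.csc_matrix
    gene_names: np.ndarray | None = None
    feature_types: np.ndarray | None = None

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.matrix = sp.csc_matrix(self.matrix)
        if self.gene_names is None:
            self.gene_names = self.gene_ids.copy()
        if self.feature_types is None:
            self.feature_types = np.asarray(
                ["Gene Expression"] * len(self.gene_ids), dtype=object
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


@dataclass
class CountMatrix:
    """Sparse genes x cells integer count matrix with identifiers.

    ``gene_names`` carries the optional second column of features.tsv
    (defaults to the ids); ``feature_types`` the optional third
    (defaults to "Gene Expression").
    """

    gene_ids: np.ndarray
    barcodes: np.ndarray
    matrix: sp.csc_matrix
    gene_names: np.ndarray | None = None
    feature_types: np.ndarray | None = None

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        m = sp.csc_matrix(self.matrix)
        if m.shape != (len(self.gene_ids), len(self.barcodes)):
            raise InvalidMatrixError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells"
            )
        if m.nnz and m.data.min() < 0:
            raise InvalidMatrixError("count matrix has negative entries")
        if not np.issubdtype(m.dtype, np.integer):
            if m.nnz and not np.all(m.data == np.floor(m.data)):
                raise InvalidMatrixError("count matrix has non-integer entries")
            m = m.astype(np.int64)
        self.matrix = m
        if self.gene_names is None:
            self.gene_names = self.gene_ids.copy()
        else:
            self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.feature_types is None:
            self.feature_types = np.asarray(
                ["Gene Expression"] * len(self.gene_ids), dtype=object
            )
        else:
            self.feature_types = np.asarray(self.feature_types, dtype=object)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FormatError(f"{stem}[.gz] not found in {dirpath}")


def _read_tsv_column_file(path: Path, min_cols: int) -> list[list[str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    rows = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(f"{path.name}: expected >= {min_cols} columns")
            rows.append(fields)
    return rows


def read_10x(directory: str | Path, cells_as_rows: bool = False) -> CountMatrix:
    """Read a 10x-style MTX directory into a :class:`CountMatrix`.

    Accepts plain or gzipped files; features.tsv may have 2 or 3
    columns.  `cells_as_rows` transposes non-standard matrices whose
    MatrixMarket rows are cells.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            m = scipy.io.mmread(_stdio.BytesIO(fh.read()))
    else:
        m = scipy.io.mmread(mtx_path)
    m = sp.csc_matrix(m)
    if cells_as_rows:
        m = sp.csc_matrix(m.T)

    features = _read_tsv_column_file(_find(directory, "features.tsv"), 1)
    barcodes = _read_tsv_column_file(_find(directory, "barcodes.tsv"), 1)
    gene_ids = np.array([f[0] for f in features], dtype=object)
    gene_names = np.array(
        [f[1] if len(f) > 1 else f[0] for f in features], dtype=object
    )
    feature_types = np.array(
        [f[2] if len(f) > 2 else "Gene Expression" for f in features], dtype=object
    )
    bc = np.array([b[0] for b in barcodes], dtype=object)

    if m.shape[0] != len(gene_ids):
        raise FormatError(
            f"features.tsv lists {len(gene_ids)} genes but matrix.mtx has "
            f"{m.shape[0]} rows"
        )
    if m.shape[1] != len(bc):
        raise FormatError(
            f"barcodes.tsv lists {len(bc)} barcodes but matrix.mtx has "
            f"{m.shape[1]} columns"
        )
    if m.nnz and not np.all(m.data == np.floor(m.data)):
        raise InvalidMatrixError("matrix.mtx contains non-integer values")
    return CountMatrix(
        gene_ids=gene_ids,
        barcodes=bc,
        matrix=m.astype(np.int64),
        gene_names=gene_names,
        feature_types=feature_types,
    )


def write_10x(
    mat: CountMatrix | NormalizedMatrix,
    directory: str | Path,
    gzip_files: bool = False,
    force: bool = False,
) -> None:
    """Write a :class:`CountMatrix` as a 10x-style MTX directory.

    Entries are written in deterministic column-major order
    ("coordinate integer" MatrixMarket). Refuses to overwrite existing
    files unless ``force``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip_files else ""
    paths = {
        "matrix": directory / f"matrix.mtx{suffix}",
        "features": directory / f"features.tsv{suffix}",
        "barcodes": directory / f"barcodes.tsv{suffix}",
    }
    if not force:
        for p in paths.values():
            if p.exists():
                raise FileExistsError(f"{p} exists; pass force=True to overwrite")

    coo = mat.matrix.tocsc().tocoo()
    order = np.lexsort((coo.row, coo.col))
    integral = np.issubdtype(coo.dtype, np.integer)
    field_name = "integer" if integral else "real"
    buf = _stdio.BytesIO()
    buf.write(f"%%MatrixMarket matrix coordinate {field_name} general\n".encode())
    buf.write(f"{mat.n_genes} {mat.n_cells} {coo.nnz}\n".encode())
    for i in order:
        v = coo.data[i] if integral else repr(float(coo.data[i]))
        buf.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {v}\n".encode())

    def _dump(path: Path, data: bytes) -> None:
        if gzip_files:
            # mtime=0 keeps output byte-stable for identical input
            with open(path, "wb") as raw, gzip.GzipFile(
                fileobj=raw, mode="wb", mtime=0
            ) as fh:
                fh.write(data)
        else:
            path.write_bytes(data)

    _dump(paths["matrix"], buf.getvalue())
    feat_lines = "".join(
        f"{i}\t{n}\t{t}\n"
        for i, n, t in zip(mat.gene_ids, mat.gene_names, mat.feature_types)
    )
    _dump(paths["features"], feat_lines.encode())
    _dump(paths["barcodes"], "".join(f"{b}\n" for b in mat.barcodes).encode())


def read_dense(path: str | Path) -> CountMatrix:
    """Read a dense TSV (gene rows, cell columns, barcode header row)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"{path}: missing or empty file")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no cell columns found")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise InvalidMatrixError(f"{path}: non-numeric entries")
    if not np.all(values == np.floor(values)):
        raise InvalidMatrixError(f"{path}: non-integer entries")
    return CountMatrix(
        gene_ids=df.index.to_numpy(dtype=object),
        barcodes=df.columns.to_numpy(dtype=object),
        matrix=sp.csc_matrix(values.astype(np.int64)),
    )


def write_dense(mat: CountMatrix, path: str | Path) -> None:
    """Write a dense TSV (gene rows, cell columns, barcode header row)."""
    df = pd.DataFrame(
        mat.matrix.toarray(),
        index=pd.Index(mat.gene_ids, name="gene_id"),
        columns=mat.barcodes,
    )
    df.to_csv(path, sep="\t")
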