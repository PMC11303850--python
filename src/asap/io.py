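"""Count-matrix container and file I/O.

The canonical in-memory orientation everywhere in this package is
genes x cells (features on rows, D x n), matching the convention of the
modelling modules.  Transposition happens only at I/O boundaries.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("asap")


@dataclass
class CountMatrix:
    """Sparse non-negative gene-by-cell (or gene-by-sample) count matrix.

    Parameters
    ----------
    values
        Non-negative matrix, shape ``(D, n)``.  Stored internally as CSC
        so that per-cell (column) access is cheap.
    genes
        Feature identifiers, length ``D``.
    samples
        Cell or sample identifiers, length ``n``.
    """

    values: sp.csc_matrix
    genes: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csc_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsc()
        D, n = self.values.shape
        if D < 1 or n < 1:
            raise ValueError(f"count matrix must be at least 1x1, got {D}x{n}")
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        if len(self.genes) != D:
            raise ValueError(
                f"{len(self.genes)} gene ids for {D} rows"
            )
        if len(self.samples) != n:
            raise ValueError(
                f"{len(self.samples)} sample ids for {n} columns"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative entries in count matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_file(path: Path) -> list[str]:
    """Read the first column of a (possibly gzipped) TSV of identifiers.

    10x features.tsv files carry (id, name, type); we keep the first
    column, disambiguated only if duplicated.
    """
    with _open_maybe_gzip(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def _find_companion(base: Path, names: Sequence[str]) -> Path | None:
    for name in names:
        for suffix in ("", ".gz"):
            cand = base / f"{name}{suffix}"
            if cand.exists():
                return cand
    return None


def read_counts(path: str | Path, fmt: str | None = None) -> CountMatrix:
    """Read a count matrix from 10x-style MTX (directory) or dense TSV.

    ``path`` may be a directory holding ``matrix.mtx[.gz]`` +
    ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``, a ``.mtx[.gz]``
    file with those companions alongside, or a TSV (genes x cells,
    header row = cell ids, first column = gene ids).

    Orientation is auto-detected from the companion files: if the MTX
    row count matches the number of barcodes rather than features, the
    matrix is transposed to genes x cells.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir() or ".mtx" in path.name:
            fmt = "mtx"
        else:
            fmt = "tsv"
    if fmt == "mtx":
        if path.is_dir():
            mtx = _find_companion(path, ["matrix.mtx"])
            if mtx is None:
                raise FileNotFoundError(f"no matrix.mtx[.gz] under {path}")
            base = path
        else:
            mtx, base = path, path.parent
        feat = _find_companion(base, ["features.tsv", "genes.tsv"])
        barc = _find_companion(base, ["barcodes.tsv"])
        if feat is None or barc is None:
            raise FileNotFoundError(
                f"missing features/genes or barcodes TSV next to {mtx}"
            )
        with _open_maybe_gzip(mtx) as fh:
            mat = scipy.io.mmread(fh)
        mat = sp.csc_matrix(mat)
        genes = _read_id_file(feat)
        cells = _read_id_file(barc)
        if mat.shape == (len(genes), len(cells)):
            pass
        elif mat.shape == (len(cells), len(genes)):
            logger.info("MTX stored cells x genes; transposing")
            mat = mat.T.tocsc()
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither "
                f"{len(genes)} features x {len(cells)} barcodes nor its transpose"
            )
        return CountMatrix(mat, genes, cells)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(
            sp.csc_matrix(df.to_numpy()), list(df.index), list(df.columns)
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_matrix(
    matrix, row_ids: Sequence[str], col_ids: Sequence[str], path: str | Path
) -> None:
    """Write a matrix as TSV with row/column headers.

    Integer matrices round-trip exactly through :func:`read_counts`;
    floats are written at 6 significant digits.
    """
    arr = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix)
    if arr.size == 0:
        raise ValueError("refusing to write an empty matrix")
    df = pd.DataFrame(arr, index=list(row_ids), columns=list(col_ids))
    if np.issubdtype(arr.dtype, np.integer) or np.all(arr == np.round(arr)):
        df = df.astype(np.int64)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format="%.6g")


def write_labels(ids: Sequence[str], labels: Sequence, path: str | Path) -> None:
    pd.DataFrame({"id": list(ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs >= 2 columns (id, label)")
    return df


def write_provenance(out_dir: str | Path, config: dict) -> None:
    """Persist the resolved run configuration for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_config.json", "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
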