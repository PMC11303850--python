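"""Random-projection binary-tree pseudobulk construction.

Cells are projected onto ``d`` random Gaussian directions, the
projections are orthogonalized (economy SVD) and row-standardized, and
each cell descends a depth-``d`` binary tree according to the signs of
its ``d`` coordinates.  Cells landing in the same leaf are summed into
a pseudobulk sample, and pseudobulk columns are depth-normalized to a
common library size of 10^4.

The projection streams over the sparse matrix in column chunks; the
full gene-by-cell matrix is never densified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix

logger = logging.getLogger("asap")

LIBRARY_SIZE = 1e4  # common depth every pseudobulk column is scaled to


@dataclass
class ProjectionBasis:
    """A d x D Gaussian random-projection basis."""

    matrix: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("basis must be a d x D matrix with d >= 1")

    @property
    def depth(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def gaussian(cls, depth: int, n_genes: int, seed: int) -> "ProjectionBasis":
        if depth < 1:
            raise ValueError("tree depth must be >= 1")
        rng = np.random.default_rng(seed)
        return cls(rng.standard_normal((depth, n_genes)), seed=seed)


@dataclass
class PseudobulkResult:
    """Pseudobulk matrix plus the leaf bookkeeping behind it.

    ``Y`` has one column per *occupied* leaf (empty leaves are dropped),
    ``leaf_ids`` gives the tree leaf behind each column, ``assignment``
    maps each cell index to its leaf and ``occupancy`` counts cells per
    occupied leaf.
    """

    Y: np.ndarray
    leaf_ids: np.ndarray
    assignment: np.ndarray
    occupancy: dict[int, int] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.Y.shape[1]

    def column_names(self) -> list[str]:
        return [f"pb_{l}" for l in self.leaf_ids]


def random_projection(
    X: CountMatrix, basis: ProjectionBasis, chunk_size: int = 10_000,
    log1p: bool = False,
) -> np.ndarray:
    """Project counts onto the basis: ``Q = R @ X`` (d x n).

    Streams over cells in chunks of ``chunk_size`` columns; exact, not
    approximate — chunking cannot change the result.
    """
    R = basis.matrix
    D, n = X.shape
    if R.shape[1] != D:
        raise ValueError(
            f"basis has {R.shape[1]} columns but matrix has {D} genes"
        )
    Q = np.empty((R.shape[0], n), dtype=np.float64)
    V = X.values
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        block = V[:, start:stop]
        if log1p:
            block = block.copy()
            block.data = np.log1p(block.data)
        Q[:, start:stop] = R @ block
    return Q


def orthogonalize_standardize(Q: np.ndarray) -> np.ndarray:
    """Orthogonalize the rows of Q by economy SVD, then standardize.

    Returns Qtilde (d x n): right singular vectors V^T with a fixed sign
    convention (largest-magnitude entry of each row positive), each row
    shifted/scaled to mean 0 and population SD 1.  If Q is rank
    deficient the trailing rows are zeroed with a warning.
    """
    Q = np.asarray(Q, dtype=np.float64)
    d, n = Q.shape
    if d > n:
        raise ValueError(
            f"cannot build {d} orthogonal directions over {n} cells (d > n)"
        )
    U, s, Vt = np.linalg.svd(Q, full_matrices=False)
    tol = s[0] * max(d, n) * np.finfo(np.float64).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < d:
        logger.warning(
            "projection matrix has rank %d < depth %d; trailing levels zeroed",
            rank, d,
        )
    Qt = np.zeros((d, n), dtype=np.float64)
    for k in range(rank):
        row = Vt[k]
        # deterministic sign: largest-magnitude coordinate made positive
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row = -row
        mu = row.mean()
        sd = row.std()
        if sd <= 1e-12:
            logger.warning("constant projection row %d; zeroed", k)
            continue
        Qt[k] = (row - mu) / sd
    return Qt


def binarize_and_assign(Qtilde: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binary codes B_kj = 1 iff Qtilde_kj > 0, and leaf ids.

    Leaf of cell j is the binary number ``sum_k 2^(k-1) B_kj`` in
    ``[0, 2^d - 1]``.  Exact zeros branch to 0.
    """
    Qtilde = np.asarray(Qtilde)
    B = (Qtilde > 0).astype(np.int8)
    d = B.shape[0]
    weights = (1 << np.arange(d)).astype(np.int64)  # 2^(k-1), k = 1..d
    leaves = weights @ B.astype(np.int64)
    return B, leaves


def aggregate_pseudobulk(X: CountMatrix, leaves: np.ndarray) -> PseudobulkResult:
    """Sum the cells of each occupied leaf into one pseudobulk column.

    Total counts are conserved exactly; empty leaves are omitted.
    """
    leaves = np.asarray(leaves)
    D, n = X.shape
    if leaves.shape[0] != n:
        raise ValueError(f"{leaves.shape[0]} leaf ids for {n} cells")
    uniq, inv = np.unique(leaves, return_inverse=True)
    L = uniq.size
    # indicator (n x L) with one 1 per row; sparse matmul does the sums
    M = sp.csr_matrix(
        (np.ones(n), (np.arange(n), inv)), shape=(n, L)
    )
    Y = np.asarray((X.values @ M).todense(), dtype=np.float64)
    occupancy = {int(l): int(c) for l, c in zip(uniq, np.bincount(inv))}
    return PseudobulkResult(
        Y=Y,
        leaf_ids=uniq.astype(np.int64),
        assignment=leaves.astype(np.int64),
        occupancy=occupancy,
        genes=list(X.genes),
    )


def normalize_pseudobulk(Y: np.ndarray, leaf_ids: np.ndarray | None = None) -> np.ndarray:
    """Scale each column to sum to the common library size 10^4."""
    Y = np.asarray(Y, dtype=np.float64)
    totals = Y.sum(axis=0)
    bad = np.nonzero(totals <= 0)[0]
    if bad.size:
        which = (
            f"leaf {leaf_ids[bad[0]]}" if leaf_ids is not None else f"column {bad[0]}"
        )
        raise ValueError(f"all-zero pseudobulk column ({which})")
    return Y * (LIBRARY_SIZE / totals)


def build_pseudobulk(
    X: CountMatrix,
    depth: int,
    seed: int,
    chunk_size: int = 10_000,
    log1p: bool = False,
) -> PseudobulkResult:
    """Full Step-1 pipeline: project, orthogonalize, binarize, aggregate,
    normalize.  Deterministic given ``(X, depth, seed)``."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth > X.n_samples:
        raise ValueError(
            f"depth {depth} exceeds number of cells {X.n_samples}"
        )
    basis = ProjectionBasis.gaussian(depth, X.n_genes, seed)
    Q = random_projection(X, basis, chunk_size=chunk_size, log1p=log1p)
    Qt = orthogonalize_standardize(Q)
    _, leaves = binarize_and_assign(Qt)
    res = aggregate_pseudobulk(X, leaves)
    res.Y = normalize_pseudobulk(res.Y, res.leaf_ids)
    return res
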