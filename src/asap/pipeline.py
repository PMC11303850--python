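"""End-to-end convenience: pseudobulk -> factorize -> cell regression."""

from __future__ import annotations

from dataclasses import dataclass

from .io import CountMatrix
from .pmf import TopicModel, fit_pmf
from .projection import TopicProportions, regress_cells
from .pseudobulk import PseudobulkResult, build_pseudobulk


@dataclass
class AsapResult:
    pseudobulk: PseudobulkResult
    model: TopicModel
    cells: TopicProportions


def run_asap(
    X: CountMatrix,
    depth: int,
    K: int,
    seed: int,
    a0: float = 1.0,
    b0: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_iter_cells: int = 10,
    chunk_size: int = 10_000,
) -> AsapResult:
    """Run the three-step pipeline on a gene-by-cell count matrix.

    Builds the depth-``depth`` random-projection pseudobulk matrix,
    fits the K-topic Gamma-Poisson factorization on it, and regresses
    every cell onto the learned dictionary.  Deterministic given
    ``(X, depth, K, seed)``.
    """
    pb = build_pseudobulk(X, depth=depth, seed=seed, chunk_size=chunk_size)
    model, _ = fit_pmf(
        pb.Y, K=K, a0=a0, b0=b0, max_iter=max_iter, tol=tol, seed=seed,
        genes=pb.genes,
    )
    cells = regress_cells(X, model, n_iter=n_iter_cells, chunk_size=chunk_size)
    return AsapResult(pseudobulk=pb, model=model, cells=cells)
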