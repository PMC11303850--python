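"""Regression of cells and bulk samples onto a fixed topic dictionary.

With the dictionary posterior held fixed, each cell j gets a
responsibility vector rho_j over topics,

    log rho_jk  =  (sum_i Y_ij E[log beta_ik]) / (sum_i Y_ij)
                   + E[log theta_jk]  + const,   sum_k rho_jk = 1,

followed by the conjugate Gamma update

    theta_jk ~ Gamma(a0 + rho_jk * sum_i Y_ij,  b0 + sum_i E[beta_ik]).

Cells are independent given the dictionary, so the computation is
embarrassingly parallel and invariant to chunking and cell order.

Bulk samples go through the identical routine after depth normalization
to the pseudobulk library size; their cell-type composition can then be
read off by counting labelled cells among nearest neighbours in the
normalized topic space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma

from .io import CountMatrix
from .pmf import GammaPosterior, TopicModel
from .pseudobulk import LIBRARY_SIZE

logger = logging.getLogger("asap")


@dataclass
class TopicProportions:
    """Per-sample topic loadings: Gamma posterior plus normalized mean."""

    theta: GammaPosterior
    proportions: np.ndarray  # rows sum to 1
    sample_ids: list[str]
    rho: np.ndarray | None = None  # final responsibilities, rows sum to 1
    dropped: list[str] = field(default_factory=list)  # zero-count samples


def responsibilities(
    scores: np.ndarray, Elog_theta: np.ndarray
) -> np.ndarray:
    """Softmax over topics of (depth-averaged data score + E[log theta]).

    ``scores`` is the per-sample row vector
    ``(sum_i Y_ij E[log beta_ik]) / (sum_i Y_ij)``; accepts a single row
    or a stacked (n x K) matrix.
    """
    W = np.atleast_2d(scores) + np.atleast_2d(Elog_theta)
    W = W - W.max(axis=1, keepdims=True)
    np.exp(W, out=W)
    W /= W.sum(axis=1, keepdims=True)
    return W if np.ndim(scores) > 1 else W[0]


def update_theta_cell(
    rho: np.ndarray,
    total_count,
    Ebeta_colsums: np.ndarray,
    a0: float,
    b0: float,
) -> GammaPosterior:
    """Per-cell Gamma update: shape a0 + rho_k * c_j, shared rate."""
    total = np.atleast_1d(np.asarray(total_count, dtype=np.float64))
    if np.any(total <= 0):
        raise ValueError("zero-total cell passed to theta update")
    rho = np.atleast_2d(rho)
    shape = a0 + rho * total[:, None]
    rate = np.broadcast_to(b0 + Ebeta_colsums, shape.shape).copy()
    return GammaPosterior(shape, rate)


def _regress_block(
    scores: np.ndarray,
    totals: np.ndarray,
    Ebeta_colsums: np.ndarray,
    a0: float,
    b0: float,
    n_iter: int,
) -> tuple[GammaPosterior, np.ndarray]:
    """Alternate rho <-> theta updates for a block of samples.

    Every operation is row-local, so results are bit-identical for any
    partition of the samples into blocks.
    """
    K = scores.shape[1]
    Elog_theta = np.zeros((scores.shape[0], K))  # uniform start: rho is beta-driven
    rate = b0 + Ebeta_colsums
    rho = None
    for _ in range(n_iter):
        rho = responsibilities(scores, Elog_theta)
        shape = a0 + rho * totals[:, None]
        Elog_theta = digamma(shape) - np.log(rate)
    theta = GammaPosterior(shape, np.broadcast_to(rate, shape.shape).copy())
    return theta, rho


def _normalized_mean(theta: GammaPosterior) -> np.ndarray:
    mean = theta.mean
    return mean / mean.sum(axis=1, keepdims=True)


def regress_cells(
    X: CountMatrix,
    model: TopicModel,
    n_iter: int = 10,
    chunk_size: int = 10_000,
    depth_average: bool = True,
) -> TopicProportions:
    """Recover per-cell topic proportions against a fixed dictionary.

    ``depth_average=True`` applies the division of the data term by the
    cell's total count as written above; ``False`` uses the raw
    count-weighted score instead (the two only differ by how strongly
    the prior-like E[log theta] term competes with the data).

    Zero-count cells cannot be scored and are dropped with a warning;
    their ids are listed in the result's ``dropped`` field.
    """
    if model.genes and model.genes != X.genes:
        raise ValueError("gene order of counts does not match the model")
    Elog_beta = model.beta.mean_log
    if Elog_beta.shape[0] != X.n_genes:
        raise ValueError(
            f"model has {Elog_beta.shape[0]} genes, matrix has {X.n_genes}"
        )
    Ebeta_colsums = model.beta.mean.sum(axis=0)
    totals_all = X.column_sums()
    keep = totals_all > 0
    dropped = [s for s, k in zip(X.samples, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-count cells", len(dropped))
    kept_idx = np.nonzero(keep)[0]
    n = kept_idx.size
    K = model.K
    shapes = np.empty((n, K))
    rates = np.empty((n, K))
    rhos = np.empty((n, K))
    V = X.values
    for start in range(0, n, chunk_size):
        idx = kept_idx[start:start + chunk_size]
        block = V[:, idx]
        scores = np.asarray((block.T @ Elog_beta))
        totals = totals_all[idx]
        if depth_average:
            scores = scores / totals[:, None]
        theta_b, rho_b = _regress_block(
            scores, totals, Ebeta_colsums, model.a0, model.b0, n_iter
        )
        shapes[start:start + idx.size] = theta_b.shape
        rates[start:start + idx.size] = theta_b.rate
        rhos[start:start + idx.size] = rho_b
    theta = GammaPosterior(shapes, rates)
    return TopicProportions(
        theta=theta,
        proportions=_normalized_mean(theta),
        sample_ids=[X.samples[i] for i in kept_idx],
        rho=rhos,
        dropped=dropped,
    )


def intersect_genes(B: CountMatrix, model: TopicModel) -> tuple[CountMatrix, TopicModel]:
    """Restrict a bulk matrix and a model to their shared gene universe,
    reordered to the model's order.  Genes absent from either side are
    dropped with a logged count."""
    if not model.genes:
        raise ValueError("model carries no gene identifiers to intersect on")
    pos = {g: i for i, g in enumerate(B.genes)}
    keep_model = [k for k, g in enumerate(model.genes) if g in pos]
    if not keep_model:
        raise ValueError("empty gene intersection between bulk data and model")
    n_drop = len(model.genes) - len(keep_model) + len(B.genes) - len(keep_model)
    if n_drop:
        logger.info("gene intersection dropped %d non-shared genes", n_drop)
    shared = [model.genes[k] for k in keep_model]
    rows = [pos[g] for g in shared]
    sub = CountMatrix(B.values[rows], shared, list(B.samples))
    beta = GammaPosterior(model.beta.shape[keep_model], model.beta.rate[keep_model])
    sub_model = TopicModel(
        beta=beta, K=model.K, a0=model.a0, b0=model.b0,
        elbo_trace=model.elbo_trace, seed=model.seed, genes=shared,
    )
    return sub, sub_model


def project_bulk(
    B: CountMatrix, model: TopicModel, n_iter: int = 10, chunk_size: int = 10_000
) -> TopicProportions:
    """Project bulk samples onto the topic space.

    Samples are depth-normalized to the pseudobulk library size (10^4)
    so the dictionary's scale assumptions carry over, then regressed
    exactly like single cells.
    """
    if model.genes and model.genes != B.genes:
        B, model = intersect_genes(B, model)
    totals = B.column_sums()
    if np.any(totals <= 0):
        raise ValueError("all-zero bulk sample after gene intersection")
    scaled = B.values.astype(np.float64).multiply(LIBRARY_SIZE / totals)
    normed = CountMatrix(sp.csc_matrix(scaled), B.genes, B.samples)
    return regress_cells(normed, model, n_iter=n_iter, chunk_size=chunk_size)


@dataclass
class DeconvolutionResult:
    """Per-bulk-sample cell-type fractions from neighbour counting."""

    fractions: np.ndarray  # bulk samples x cell types, rows sum to 1
    cell_types: list[str]
    sample_ids: list[str]
    k_neighbors: int


def deconvolve_by_neighbors(
    theta_bulk: TopicProportions,
    theta_cells: TopicProportions,
    labels,
    k: int = 100,
    chunk_size: int = 1_000,
) -> DeconvolutionResult:
    """Estimate composition by counting cell-type labels among the k
    nearest cells (Euclidean distance in normalized topic space).

    Distance ties at the k-th neighbour are broken by cell index, so the
    result is reproducible.
    """
    P_bulk = np.asarray(theta_bulk.proportions)
    P_cells = np.asarray(theta_cells.proportions)
    labels = np.asarray(labels)
    n_cells = P_cells.shape[0]
    if labels.shape[0] != n_cells:
        raise ValueError(f"{labels.shape[0]} labels for {n_cells} cells")
    if k > n_cells:
        raise ValueError(f"k={k} exceeds number of cells {n_cells}")
    types = sorted(set(labels.tolist()))
    type_idx = {t: c for c, t in enumerate(types)}
    codes = np.array([type_idx[t] for t in labels.tolist()])
    fractions = np.empty((P_bulk.shape[0], len(types)))
    for start in range(0, P_bulk.shape[0], chunk_size):
        block = P_bulk[start:start + chunk_size]
        d2 = (
            np.sum(block**2, axis=1)[:, None]
            - 2.0 * block @ P_cells.T
            + np.sum(P_cells**2, axis=1)[None, :]
        )
        # stable argsort: equal distances resolve to the lower cell index
        nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
        for r, row in enumerate(nearest):
            fractions[start + r] = np.bincount(
                codes[row], minlength=len(types)
            ) / k
    return DeconvolutionResult(
        fractions=fractions,
        cell_types=[str(t) for t in types],
        sample_ids=list(theta_bulk.sample_ids),
        k_neighbors=k,
    )
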