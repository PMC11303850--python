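"""Gamma-Poisson matrix factorization by mean-field variational inference.

Model: Y_ij ~ Poisson(sum_k beta_ik theta_jk) with independent
Gamma(a0, b0) priors on every beta_ik (gene-by-topic dictionary) and
theta_jk (sample-by-topic loading).  The likelihood is non-conjugate,
so each count is augmented with multinomial responsibilities z_ijk
(sum_k z_ijk = 1) that split Y_ij across topics; coordinate ascent on
the resulting mean-field bound has closed-form Gamma updates.

The responsibilities are only ever computed on the nonzeros of Y —
zeros contribute nothing to the count-weighted sufficient statistics —
so the D x L x K tensor is never materialized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln

logger = logging.getLogger("asap")

LOG_FLOOR = 1e-300  # clamp for log arguments


@dataclass
class GammaPosterior:
    """Element-wise Gamma variational posterior with derived moments."""

    shape: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.shape = np.asarray(self.shape, dtype=np.float64)
        self.rate = np.asarray(self.rate, dtype=np.float64)
        if self.shape.shape != self.rate.shape:
            raise ValueError("shape/rate dimension mismatch")
        if np.any(self.shape <= 0) or np.any(self.rate <= 0):
            raise ValueError("Gamma parameters must be positive")

    @property
    def mean(self) -> np.ndarray:
        """E[x] = a / b."""
        return self.shape / self.rate

    @property
    def mean_log(self) -> np.ndarray:
        """E[log x] = psi(a) - log b."""
        return digamma(self.shape) - np.log(self.rate)

    def entropy(self) -> np.ndarray:
        a, b = self.shape, self.rate
        return a - np.log(b) + gammaln(a) + (1.0 - a) * digamma(a)


@dataclass
class SufficientStats:
    """Count-weighted responsibility sums.

    ``S_theta[j, k] = sum_i Y_ij z_ijk`` and
    ``S_beta[i, k] = sum_j Y_ij z_ijk``; summing either over k recovers
    the sample/gene totals of Y (counts are conserved across topics).
    """

    S_theta: np.ndarray
    S_beta: np.ndarray
    loglik_term: float = 0.0  # sum_ij Y_ij * logsumexp_k(Elog_beta + Elog_theta)


@dataclass
class TopicModel:
    """Fitted dictionary posterior plus hyperparameters and ELBO trace."""

    beta: GammaPosterior
    K: int
    a0: float
    b0: float
    elbo_trace: list[float] = field(default_factory=list)
    seed: int | None = None
    genes: list[str] = field(default_factory=list)


def _as_coo(Y) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]:
    if sp.issparse(Y):
        C = Y.tocoo()
        return C.row, C.col, C.data.astype(np.float64), Y.shape
    Y = np.asarray(Y, dtype=np.float64)
    ii, jj = np.nonzero(Y)
    return ii, jj, Y[ii, jj], Y.shape


def auxiliary_stats(
    Y,
    Elog_beta: np.ndarray,
    Elog_theta: np.ndarray,
    chunk_size: int = 500_000,
) -> SufficientStats:
    """Responsibility softmax over topics at every nonzero of Y.

    For each nonzero (i, j): z_ij. = softmax_k(Elog_beta_ik +
    Elog_theta_jk), accumulated into S_theta and S_beta weighted by
    Y_ij.  Works in nonzero chunks; memory is O(chunk * K).
    """
    Elog_beta = np.asarray(Elog_beta, dtype=np.float64)
    Elog_theta = np.asarray(Elog_theta, dtype=np.float64)
    if not (np.all(np.isfinite(Elog_beta)) and np.all(np.isfinite(Elog_theta))):
        raise ValueError("non-finite log-moment inputs")
    ii, jj, vv, (D, L) = _as_coo(Y)
    if np.any(vv < 0):
        raise ValueError("negative entries in Y")
    K = Elog_beta.shape[1]
    if Elog_beta.shape[0] != D or Elog_theta.shape != (L, K):
        raise ValueError("inconsistent shapes between Y and log-moments")
    S_theta = np.zeros((L, K))
    S_beta = np.zeros((D, K))
    loglik = 0.0
    for start in range(0, ii.size, chunk_size):
        sl = slice(start, min(start + chunk_size, ii.size))
        i, j, v = ii[sl], jj[sl], vv[sl]
        W = Elog_beta[i] + Elog_theta[j]
        m = W.max(axis=1, keepdims=True)
        np.exp(W - m, out=W)
        tot = W.sum(axis=1)
        loglik += float(v @ (np.log(tot) + m.ravel()))
        W *= (v / tot)[:, None]
        for k in range(K):
            S_beta[:, k] += np.bincount(i, weights=W[:, k], minlength=D)
            S_theta[:, k] += np.bincount(j, weights=W[:, k], minlength=L)
    return SufficientStats(S_theta=S_theta, S_beta=S_beta, loglik_term=loglik)


def update_theta(
    stats: SufficientStats, Ebeta: np.ndarray, a0: float, b0: float
) -> GammaPosterior:
    """theta_jk | z, beta ~ Gamma(a0 + S_theta_jk, b0 + sum_i E[beta_ik]).

    The rate is shared across samples within a topic.
    """
    if a0 <= 0 or b0 <= 0:
        raise ValueError("prior parameters must be positive")
    shape = a0 + stats.S_theta
    rate = np.broadcast_to(
        b0 + Ebeta.sum(axis=0), shape.shape
    ).copy()
    return GammaPosterior(shape, rate)


def update_beta(
    stats: SufficientStats, Etheta: np.ndarray, a0: float, b0: float
) -> GammaPosterior:
    """beta_ik | z, theta ~ Gamma(a0 + S_beta_ik, b0 + sum_j E[theta_jk])."""
    if a0 <= 0 or b0 <= 0:
        raise ValueError("prior parameters must be positive")
    shape = a0 + stats.S_beta
    rate = np.broadcast_to(
        b0 + Etheta.sum(axis=0), shape.shape
    ).copy()
    return GammaPosterior(shape, rate)


def elbo(
    Y,
    beta: GammaPosterior,
    theta: GammaPosterior,
    stats: SufficientStats,
    a0: float,
    b0: float,
) -> float:
    """Evidence lower bound up to constants independent of the
    variational parameters (the sum of log Y_ij! and the Gamma prior
    normalizers are dropped).

    At the responsibility optimum the data term collapses to
    ``sum_ij Y_ij logsumexp_k(E[log beta_ik] + E[log theta_jk])``,
    which ``auxiliary_stats`` already accumulated.
    """
    Eb, Et = beta.mean, theta.mean
    poisson_mass = float(Eb.sum(axis=0) @ Et.sum(axis=0))
    def gamma_terms(post: GammaPosterior) -> float:
        return float(
            np.sum((a0 - 1.0) * post.mean_log - b0 * post.mean)
            + post.entropy().sum()
        )
    return stats.loglik_term - poisson_mass + gamma_terms(beta) + gamma_terms(theta)


def fit_pmf(
    Y,
    K: int,
    a0: float = 1.0,
    b0: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    genes: list[str] | None = None,
    verbose: bool = False,
) -> tuple[TopicModel, GammaPosterior]:
    """Fit the factorization by coordinate ascent.

    One iteration recomputes the responsibilities, then the theta and
    beta posteriors, each a closed-form coordinate maximum; the ELBO is
    therefore non-decreasing along the trace.  Initialization puts
    seeded noise only in the dictionary shapes — loadings start
    symmetric — which keeps the fit equivariant under sample
    permutations.  Stops when the relative ELBO change drops below
    ``tol`` or after ``max_iter`` iterations.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    ii, jj, vv, (D, L) = _as_coo(Y)
    if ii.size == 0:
        raise ValueError("empty count matrix")
    if K > min(D, L):
        warnings.warn(
            f"K={K} exceeds min(D, L)={min(D, L)}; model over-parameterized"
        )
    rng = np.random.default_rng(seed)
    grand_mean = vv.sum() / (D * L)
    beta = GammaPosterior(
        a0 + 0.1 * rng.uniform(size=(D, K)),
        np.full((D, K), b0 + np.sqrt(grand_mean / K) * L),
    )
    theta = GammaPosterior(
        np.full((L, K), a0),
        np.full((L, K), b0 + np.sqrt(grand_mean / K) * D),
    )
    trace: list[float] = []
    for it in range(max_iter):
        stats = auxiliary_stats(Y, beta.mean_log, theta.mean_log)
        trace.append(elbo(Y, beta, theta, stats, a0, b0))
        theta = update_theta(stats, beta.mean, a0, b0)
        beta = update_beta(stats, theta.mean, a0, b0)
        if verbose and it % 50 == 0:
            logger.info("iter %d  elbo %.6f", it, trace[-1])
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) < tol * abs(prev):
                break
    model = TopicModel(
        beta=beta, K=K, a0=a0, b0=b0, elbo_trace=trace, seed=seed,
        genes=list(genes) if genes is not None else [],
    )
    return model, theta


def to_multinomial_scale(
    beta_mean: np.ndarray, theta_mean: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale to the multinomial topic-model parameterization.

    The Poisson factorization is scale-unidentifiable per topic
    (beta_k, theta_k) -> (s beta_k, theta_k / s); absorbing the scales
    gives columns of beta summing to 1 (gene distribution per topic)
    and rows of theta summing to 1 (topic proportions per sample).
    """
    beta_mean = np.asarray(beta_mean, dtype=np.float64)
    theta_mean = np.asarray(theta_mean, dtype=np.float64)
    col = beta_mean.sum(axis=0)
    if np.any(col <= 0):
        raise ValueError("all-zero dictionary column")
    beta_norm = beta_mean / col
    scaled = theta_mean * col  # topic scale moves into the loadings
    row = scaled.sum(axis=1, keepdims=True)
    if np.any(row <= 0):
        raise ValueError("all-zero loading row")
    return beta_norm, scaled / row
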