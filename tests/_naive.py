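"""Independent dense reference implementations used as test oracles.

These deliberately materialize the full D x L x K responsibility tensor
and follow the update equations written out naively, so they share no
code path with the package's sparse-aware implementation.
"""

import numpy as np
from scipy.special import digamma, gammaln


def naive_responsibilities(Elog_beta, Elog_theta):
    D, K = Elog_beta.shape
    L = Elog_theta.shape[0]
    Z = np.empty((D, L, K))
    for i in range(D):
        for j in range(L):
            w = Elog_beta[i] + Elog_theta[j]
            w = np.exp(w - w.max())
            Z[i, j] = w / w.sum()
    return Z


def naive_elbo(Y, b_shape, b_rate, t_shape, t_rate, a0, b0):
    """Mean-field bound with the responsibilities at their optimum,
    dropping the same constants (log Y! and prior normalizers)."""
    Elog_b = digamma(b_shape) - np.log(b_rate)
    Elog_t = digamma(t_shape) - np.log(t_rate)
    Eb, Et = b_shape / b_rate, t_shape / t_rate
    D, L = Y.shape
    data = 0.0
    for i in range(D):
        for j in range(L):
            if Y[i, j] > 0:
                w = Elog_b[i] + Elog_t[j]
                m = w.max()
                data += Y[i, j] * (m + np.log(np.exp(w - m).sum()))
    data -= float(Eb.sum(axis=0) @ Et.sum(axis=0))

    def gam(shape, rate, Elog, E):
        ent = shape - np.log(rate) + gammaln(shape) + (1 - shape) * digamma(shape)
        return np.sum((a0 - 1) * Elog - b0 * E) + ent.sum()

    return data + gam(b_shape, b_rate, Elog_b, Eb) + gam(t_shape, t_rate, Elog_t, Et)


def naive_fit_pmf(Y, K, a0=1.0, b0=1.0, max_iter=200, seed=0):
    """Coordinate ascent with the full tensor; mirrors the package's
    initialization so trajectories are comparable, but every update is
    coded independently from the dense equations."""
    Y = np.asarray(Y, dtype=float)
    D, L = Y.shape
    rng = np.random.default_rng(seed)
    grand_mean = Y.sum() / (D * L)
    b_shape = a0 + 0.1 * rng.uniform(size=(D, K))
    b_rate = np.full((D, K), b0 + np.sqrt(grand_mean / K) * L)
    t_shape = np.full((L, K), a0)
    t_rate = np.full((L, K), b0 + np.sqrt(grand_mean / K) * D)
    trace = []
    for _ in range(max_iter):
        Elog_b = digamma(b_shape) - np.log(b_rate)
        Elog_t = digamma(t_shape) - np.log(t_rate)
        Z = naive_responsibilities(Elog_b, Elog_t)
        trace.append(naive_elbo(Y, b_shape, b_rate, t_shape, t_rate, a0, b0))
        # theta update
        S_theta = np.einsum("ij,ijk->jk", Y, Z)
        t_shape = a0 + S_theta
        t_rate = np.tile(b0 + (b_shape / b_rate).sum(axis=0), (L, 1))
        # beta update
        S_beta = np.einsum("ij,ijk->ik", Y, Z)
        b_shape = a0 + S_beta
        b_rate = np.tile(b0 + (t_shape / t_rate).sum(axis=0), (D, 1))
    return b_shape, b_rate, t_shape, t_rate, trace


def naive_theta_given_beta(Y, b_shape, b_rate, a0=1.0, b0=1.0, n_iter=50):
    """Full Step-2-style inference with the dictionary frozen: per-count
    responsibilities (not the collapsed per-cell approximation)."""
    Y = np.asarray(Y, dtype=float)
    D, L = Y.shape
    K = b_shape.shape[1]
    Elog_b = digamma(b_shape) - np.log(b_rate)
    Eb = b_shape / b_rate
    t_shape = np.full((L, K), a0)
    t_rate = np.full((L, K), b0 + Eb.sum())
    for _ in range(n_iter):
        Elog_t = digamma(t_shape) - np.log(t_rate)
        Z = naive_responsibilities(Elog_b, Elog_t)
        S_theta = np.einsum("ij,ijk->jk", Y, Z)
        t_shape = a0 + S_theta
        t_rate = np.tile(b0 + Eb.sum(axis=0), (L, 1))
    return t_shape, t_rate


def brute_force_ari(a, b):
    """Hubert-Arabie ARI from pair-counting over the contingency table."""
    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    n = a.size
    cont = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua])
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(cont).sum()
    sum_a = comb(cont.sum(axis=1)).sum()
    sum_b = comb(cont.sum(axis=0)).sum()
    total = comb(n)
    expected = sum_a * sum_b / total
    max_idx = 0.5 * (sum_a + sum_b)
    if max_idx == expected:
        return 1.0
    return (sum_ij - expected) / (max_idx - expected)


def brute_force_nmi(a, b):
    """Mutual information over the joint distribution, normalized by the
    arithmetic mean of the marginal entropies."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    ua, ub = np.unique(a), np.unique(b)
    pj = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua]) / n
    pa, pb = pj.sum(axis=1), pj.sum(axis=0)
    mi = 0.0
    for r in range(len(ua)):
        for c in range(len(ub)):
            if pj[r, c] > 0:
                mi += pj[r, c] * np.log(pj[r, c] / (pa[r] * pb[c]))
    ent = lambda p: -np.sum(p[p > 0] * np.log(p[p > 0]))
    ha, hb = ent(pa), ent(pb)
    if ha == 0 and hb == 0:
        return 1.0
    denom = 0.5 * (ha + hb)
    return mi / denom if denom > 0 else 0.0


def set_partitions(n):
    """All set partitions of range(n) as label vectors (restricted
    growth strings)."""
    def rec(prefix, m):
        idx = len(prefix)
        if idx == n:
            yield list(prefix)
            return
        for v in range(m + 1):
            yield from rec(prefix + [v], max(m, v + 1))
    yield from rec([], 0)
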