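"""Cell-level regression onto a fixed dictionary, bulk projection, and
neighbour-counting deconvolution."""

import logging

import numpy as np
import pytest
import scipy.sparse as sp

import asap
from asap.pmf import GammaPosterior, TopicModel
from asap.projection import _regress_block, responsibilities, update_theta_cell

from _naive import naive_theta_given_beta


def make_model(Elog_beta=None, Ebeta=None, K=2, D=2, genes=None):
    """Wrap explicit moments into a TopicModel by inverting the Gamma
    moment map (rate = 1 makes shape the mean)."""
    if Ebeta is None:
        Ebeta = np.ones((D, K))
    shape = np.asarray(Ebeta, dtype=float)
    return TopicModel(
        beta=GammaPosterior(shape, np.ones_like(shape)),
        K=shape.shape[1], a0=1.0, b0=1.0,
        genes=genes or [],
    )


class TestResponsibilities:
    def test_formula_forced_example(self):
        # cell (2, 0); Elog_beta columns (0,-10) and (-10,0); Elog_theta 0
        Elog_beta = np.array([[0.0, -10.0], [-10.0, 0.0]])
        y = np.array([2.0, 0.0])
        scores = (y @ Elog_beta) / y.sum()
        rho = responsibilities(scores, np.zeros(2))
        np.testing.assert_allclose(rho, [0.9999546, 4.5398e-5], rtol=1e-3)
        assert rho.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_topic(self):
        assert responsibilities(np.array([1.7]), np.zeros(1)) == pytest.approx(1.0)

    def test_uniform_inputs_give_uniform_rho(self):
        rho = responsibilities(np.full(4, -2.0), np.full(4, 0.3))
        np.testing.assert_allclose(rho, 0.25)


class TestUpdateThetaCell:
    def test_plug_in(self):
        post = update_theta_cell(
            np.array([0.25, 0.75]), 8.0, np.array([2.0, 2.0]), a0=1.0, b0=1.0
        )
        np.testing.assert_allclose(post.shape, [[3.0, 7.0]])
        np.testing.assert_allclose(post.rate, [[3.0, 3.0]])

    def test_concentrated_rho(self):
        post = update_theta_cell(
            np.array([1.0, 0.0]), 10.0, np.array([1.0, 1.0]), a0=0.5, b0=1.0
        )
        np.testing.assert_allclose(post.shape, [[10.5, 0.5]])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            update_theta_cell(np.array([1.0]), 0.0, np.array([1.0]), 1.0, 1.0)


class TestRegressCells:
    def test_duplicated_cell_gets_identical_rows(self):
        col = np.array([[3], [1], [0], [5]])
        X = asap.CountMatrix(
            sp.csc_matrix(np.tile(col, (1, 5))),
            [f"g{i}" for i in range(4)], [f"c{j}" for j in range(5)],
        )
        rng = np.random.default_rng(0)
        model = make_model(Ebeta=rng.gamma(1, 1, (4, 3)))
        res = asap.regress_cells(X, model)
        for j in range(1, 5):
            np.testing.assert_array_equal(res.proportions[0], res.proportions[j])

    def test_chunking_bit_identical(self, random_counts):
        rng = np.random.default_rng(1)
        model = make_model(Ebeta=rng.gamma(1, 1, (50, 4)))
        a = asap.regress_cells(random_counts, model, chunk_size=1)
        b = asap.regress_cells(random_counts, model, chunk_size=10_000)
        np.testing.assert_array_equal(a.proportions, b.proportions)
        np.testing.assert_array_equal(a.rho, b.rho)

    def test_zero_count_cells_dropped_with_warning(self, caplog):
        vals = np.array([[1, 0], [2, 0]])
        X = asap.CountMatrix(sp.csc_matrix(vals), ["g0", "g1"], ["c0", "c1"])
        model = make_model(D=2, K=2)
        with caplog.at_level(logging.WARNING, logger="asap"):
            res = asap.regress_cells(X, model)
        assert res.dropped == ["c1"]
        assert res.proportions.shape == (1, 2)
        assert "zero-count" in caplog.text

    def test_gene_order_mismatch_raises(self, random_counts):
        model = make_model(
            Ebeta=np.ones((50, 2)), genes=[f"h{i}" for i in range(50)]
        )
        with pytest.raises(ValueError, match="gene order"):
            asap.regress_cells(random_counts, model)

    def test_pure_cells_assigned_to_true_topic(self):
        """Cells drawn from single topics of a 2-topic dictionary get
        > 0.9 of their proportion mass on the true topic."""
        rng = np.random.default_rng(21)
        D = 60
        beta = np.zeros((D, 2))
        beta[:30, 0] = rng.gamma(5, 1, 30)
        beta[30:, 1] = rng.gamma(5, 1, 30)
        beta += 0.01
        cells, true_topic = [], []
        for j in range(100):
            k = j % 2
            lam = beta[:, k] / beta[:, k].sum() * 2000
            cells.append(rng.poisson(lam))
            true_topic.append(k)
        X = asap.CountMatrix(
            sp.csc_matrix(np.array(cells).T),
            [f"g{i}" for i in range(D)], [f"c{j}" for j in range(100)],
        )
        model = make_model(Ebeta=beta)
        res = asap.regress_cells(X, model)
        hits = res.proportions[np.arange(100), true_topic] > 0.9
        assert hits.mean() >= 0.95

    def test_rho_rows_sum_to_one(self, random_counts):
        model = make_model(
            Ebeta=np.random.default_rng(2).gamma(1, 1, (50, 5))
        )
        res = asap.regress_cells(random_counts, model)
        np.testing.assert_allclose(res.rho.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(res.proportions.sum(axis=1), 1.0, atol=1e-8)

    def test_consistent_with_frozen_beta_full_inference(self):
        """The collapsed per-cell bound tracks full per-count inference
        with the dictionary frozen (normalized loadings correlate > 0.99)
        in the near-pure-cell regime the method targets; for strongly
        mixed cells the collapsed bound concentrates harder."""
        rng = np.random.default_rng(33)
        D, n, K = 40, 15, 3
        beta_mean = np.full((D, K), 0.05)
        for k in range(K):
            beta_mean[k * 13:(k + 1) * 13, k] = rng.gamma(5, 1, 13)
        beta_shape = beta_mean * 2.0
        beta_rate = np.full((D, K), 2.0)
        dominant = np.full((n, K), 0.05)
        dominant[np.arange(n), rng.integers(0, K, n)] = 0.9
        dominant /= dominant.sum(axis=1, keepdims=True)
        lam = (beta_mean / beta_mean.sum(0)) @ dominant.T * 300
        Y = rng.poisson(lam).astype(float)
        Y[:, Y.sum(axis=0) == 0] += 1
        X = asap.CountMatrix(
            sp.csc_matrix(Y), [f"g{i}" for i in range(D)],
            [f"c{j}" for j in range(n)],
        )
        model = TopicModel(
            beta=GammaPosterior(beta_shape, beta_rate), K=K, a0=1.0, b0=1.0
        )
        res = asap.regress_cells(X, model, n_iter=50)
        t_shape, t_rate = naive_theta_given_beta(Y, beta_shape, beta_rate, n_iter=50)
        full = t_shape / t_rate
        full = full / full.sum(axis=1, keepdims=True)
        for j in range(n):
            assert np.corrcoef(res.proportions[j], full[j])[0, 1] > 0.99


class TestProjectBulk:
    def test_pseudobulk_column_round_trip(self, small_benchmark):
        X, _ = small_benchmark
        pb = asap.build_pseudobulk(X, depth=3, seed=1)
        model, _ = asap.fit_pmf(pb.Y, K=3, seed=1, max_iter=80, genes=pb.genes)
        bulk = asap.CountMatrix(
            sp.csc_matrix(pb.Y[:, :2]), pb.genes, ["b0", "b1"]
        )
        got = asap.project_bulk(bulk, model)
        direct = asap.regress_cells(
            asap.CountMatrix(sp.csc_matrix(pb.Y[:, :2]), pb.genes, ["b0", "b1"]),
            model,
        )
        np.testing.assert_allclose(got.proportions, direct.proportions, rtol=1e-9)

    def test_mixture_recovers_half_and_half(self):
        """Equal mixture of two exchangeable topic-pure profiles projects
        to (0.5, 0.5).  The topics share one value set on disjoint gene
        blocks so neither is favoured a priori; only Poisson noise on the
        bulk counts perturbs the balance."""
        rng = np.random.default_rng(55)
        D = 80
        v = rng.gamma(5, 1, 40)
        beta = np.full((D, 2), 0.01)
        beta[:40, 0] = v
        beta[40:, 1] = v
        pure0 = beta[:, 0] / beta[:, 0].sum()
        pure1 = beta[:, 1] / beta[:, 1].sum()
        bulk_counts = rng.poisson(0.5 * pure0 * 5e4 + 0.5 * pure1 * 5e4)
        B = asap.CountMatrix(
            sp.csc_matrix(bulk_counts[:, None]),
            [f"g{i}" for i in range(D)], ["bulk0"],
        )
        # concentrated posterior so E[log beta] ~ log E[beta]
        model = TopicModel(
            beta=GammaPosterior(100.0 * beta, np.full((D, 2), 100.0)),
            K=2, a0=1.0, b0=1.0, genes=[f"g{i}" for i in range(D)],
        )
        res = asap.project_bulk(B, model)
        np.testing.assert_allclose(res.proportions[0], [0.5, 0.5], atol=0.1)

    def test_empty_intersection_raises(self):
        B = asap.CountMatrix(sp.csc_matrix(np.ones((2, 1))), ["x", "y"], ["b"])
        model = make_model(D=2, genes=["g0", "g1"])
        with pytest.raises(ValueError, match="intersection"):
            asap.project_bulk(B, model)


def props(P, ids=None):
    P = np.asarray(P, dtype=float)
    return asap.TopicProportions(
        theta=GammaPosterior(np.maximum(P, 1e-9), np.ones_like(P)),
        proportions=P / P.sum(axis=1, keepdims=True),
        sample_ids=ids or [f"s{i}" for i in range(P.shape[0])],
    )


class TestDeconvolve:
    def test_single_label_gives_fraction_one(self):
        cells = props(np.random.default_rng(0).dirichlet([1, 1], size=30))
        bulk = props(np.array([[0.5, 0.5]]))
        res = asap.deconvolve_by_neighbors(bulk, cells, ["T"] * 30, k=10)
        np.testing.assert_allclose(res.fractions, [[1.0]])

    def test_k_one_is_nearest_indicator(self):
        cells = props(np.array([[1.0, 0.0], [0.0, 1.0]]))
        bulk = props(np.array([[0.9, 0.1]]))
        res = asap.deconvolve_by_neighbors(bulk, cells, ["A", "B"], k=1)
        assert res.fractions[0, res.cell_types.index("A")] == 1.0

    def test_rows_are_probability_vectors(self):
        rng = np.random.default_rng(4)
        cells = props(rng.dirichlet([1] * 3, size=50))
        bulk = props(rng.dirichlet([1] * 3, size=7))
        labels = rng.choice(["A", "B", "C"], size=50)
        res = asap.deconvolve_by_neighbors(bulk, cells, labels, k=20)
        np.testing.assert_allclose(res.fractions.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(res.fractions >= 0)

    def test_k_too_large_raises(self):
        cells = props(np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="exceeds"):
            asap.deconvolve_by_neighbors(cells, cells, ["A"], k=2)

    def test_distance_ties_break_by_index(self):
        cells = props(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        bulk = props(np.array([[1.0, 0.0]]))
        res = asap.deconvolve_by_neighbors(bulk, cells, ["A", "B", "C"], k=1)
        assert res.fractions[0, res.cell_types.index("A")] == 1.0
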