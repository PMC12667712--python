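import numpy as np
import pytest
import scipy.sparse as sp

import srtjoint as sj
from srtjoint.data_io import PairedData, SRTSlice
from srtjoint.model import (
    ModelError,
    _build_problem,
    _init_raw,
    _loss_and_grad,
)
from conftest import assert_model_valid


def brute_poisson(Y, Z, floor=1e-8):
    total = 0.0
    for i in range(Y.shape[0]):
        for j in range(Y.shape[1]):
            total += Z[i, j] - Y[i, j] * np.log(max(Z[i, j], floor))
    return total


class TestPoissonLoss:
    def test_zero_observation(self):
        assert sj.poisson_loss(np.array([[0.0]]), np.array([[1.0]])) == 1.0

    def test_hand_value(self):
        # 2 - 2 ln 2
        val = sj.poisson_loss(np.array([[2.0]]), np.array([[2.0]]))
        assert val == pytest.approx(2 - 2 * np.log(2), abs=1e-12)

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            Y = rng.poisson(3.0, (5, 5)).astype(float)
            Z = rng.gamma(2.0, 1.0, (5, 5))
            assert sj.poisson_loss(Y, Z) == pytest.approx(
                brute_poisson(Y, Z), rel=1e-12
            )

    def test_minimized_at_observation(self):
        rng = np.random.default_rng(1)
        Y = rng.gamma(3.0, 1.0, (4, 4)) + 0.5
        base = sj.poisson_loss(Y, Y)
        for _ in range(20):
            Z = Y * np.exp(rng.normal(0, 0.2, Y.shape))
            assert sj.poisson_loss(Y, Z) >= base

    def test_invalid_inputs(self):
        with pytest.raises(ModelError):
            sj.poisson_loss(np.zeros((2, 2)), np.zeros((3, 2)))
        with pytest.raises(ModelError):
            sj.poisson_loss(np.array([[np.nan]]), np.array([[1.0]]))


class TestEntropy:
    def test_schedule(self):
        assert sj.entropy_weight(0, 500) == 1.0
        assert sj.entropy_weight(5000, 1000) == pytest.approx(np.exp(5))
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = rng.integers(0, 5000)
            lam = rng.uniform(10, 2000)
            assert sj.entropy_weight(k + 1, lam) > sj.entropy_weight(k, lam)
        with pytest.raises(ModelError):
            sj.entropy_weight(10, 0.0)

    def test_entropy_term_values(self):
        assert sj.entropy_term(np.eye(2)) == 0.0
        assert sj.entropy_term(np.array([[0.5, 0.5]])) == pytest.approx(np.log(2))
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(4), size=10)
        brute = -sum(
            p * np.log(p) for row in P for p in row if p > 0
        )
        assert sj.entropy_term(P) == pytest.approx(brute, rel=1e-12)
        with pytest.raises(ModelError):
            sj.entropy_term(np.array([[-0.1, 1.1]]))


def tiny_pair(ax, av, gamma, x_genes, v_genes):
    n_x = ax.shape[0]
    n_v = av.shape[0]
    xen = SRTSlice(
        counts=sp.csr_matrix(ax),
        coords=np.arange(2 * n_x, dtype=float).reshape(n_x, 2),
        gene_names=x_genes,
        spot_ids=[f"x{i}" for i in range(n_x)],
    )
    vis = SRTSlice(
        counts=sp.csr_matrix(av),
        coords=np.arange(2 * n_v, dtype=float).reshape(n_v, 2),
        gene_names=v_genes,
        spot_ids=[f"v{i}" for i in range(n_v)],
    )
    return PairedData(
        xenium=xen, visium=vis, gamma=sp.csr_matrix(gamma), gene_universe=v_genes
    )


class TestTotalLoss:
    def setup_method(self):
        # 2 high-res spots, 1 low-res spot, 2 genes, h = 1
        self.data = tiny_pair(
            ax=np.array([[1, 0], [2, 3]]),
            av=np.array([[3, 3]]),
            gamma=np.array([[1.0], [1.0]]),
            x_genes=["a", "b"],
            v_genes=["a", "b"],
        )
        self.params = dict(
            N=np.array([2.0, 4.0]),
            P=np.array([[1.0], [1.0]]),
            Q=np.array([[0.4, 0.6]]),
            M=np.array([[1.5], [2.5]]),
        )

    def test_equals_sum_of_two_poisson_terms(self):
        ZX = np.array([[0.8, 1.2], [1.6, 2.4]])
        ZV = np.array([[1.6, 2.4]])
        expected = sj.poisson_loss(
            self.data.xenium.counts.toarray(), ZX
        ) + sj.poisson_loss(self.data.visium.counts.toarray(), ZV)
        got = sj.total_loss(self.data, **self.params)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_counts_gives_pure_mean_mass(self):
        data = tiny_pair(
            ax=np.zeros((2, 2), dtype=int),
            av=np.zeros((1, 2), dtype=int),
            gamma=np.array([[1.0], [1.0]]),
            x_genes=["a", "b"],
            v_genes=["a", "b"],
        )
        N, P, Q, M = (self.params[k] for k in ("N", "P", "Q", "M"))
        ZX = (N[:, None] * P) @ Q
        ZV = M.T @ (P @ Q)
        got = sj.total_loss(data, **self.params)
        assert got == pytest.approx(ZX.sum() + ZV.sum(), rel=1e-12)

    def test_unit_platform_scaling_is_identity(self):
        base = sj.total_loss(self.data, **self.params)
        scaled = sj.total_loss(self.data, phi=np.ones(2), **self.params)
        assert scaled == base


class TestReparameterization:
    def test_rank1_by_hand(self):
        raw = sj.RawFactorization(
            W=np.array([[1.0]]), H=np.array([[2.0, 2.0]]), K=np.zeros((1, 1))
        )
        N, P, Q, M = sj.raw_to_scaled(raw)
        assert N.tolist() == [4.0]
        assert P.tolist() == [[1.0]]
        assert Q.tolist() == [[0.5, 0.5]]

    def test_product_preserved_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            W = rng.gamma(1.0, 1.0, (10, 3))
            H = rng.gamma(1.0, 1.0, (3, 8))
            K = rng.gamma(1.0, 1.0, (10, 4))
            raw = sj.RawFactorization(W=W, H=H, K=K)
            N, P, Q, M = sj.raw_to_scaled(raw)
            assert np.max(np.abs((N[:, None] * P) @ Q - W @ H)) < 1e-10
            np.testing.assert_allclose(M, N[:, None] * K)

    def test_roundtrip_reproduces_product(self):
        rng = np.random.default_rng(5)
        W = rng.gamma(1.0, 1.0, (6, 2))
        W[3] = 0.0  # zero row: N = 0, uniform P row
        H = rng.gamma(1.0, 1.0, (2, 5))
        K = rng.gamma(1.0, 1.0, (6, 3))
        N, P, Q, M = sj.raw_to_scaled(sj.RawFactorization(W=W, H=H, K=K))
        assert N[3] == 0.0
        np.testing.assert_allclose(P[3], 0.5)
        back = sj.scaled_to_raw(N, P, Q, M)
        np.testing.assert_allclose(back.W @ back.H, W @ H, atol=1e-10)

    def test_zero_expression_factor_rejected(self):
        with pytest.raises(ModelError):
            sj.raw_to_scaled(
                sj.RawFactorization(
                    W=np.ones((2, 2)),
                    H=np.array([[1.0, 1.0], [0.0, 0.0]]),
                    K=np.zeros((2, 1)),
                )
            )


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self, small_pair):
        data, _ = small_pair
        cfg = sj.ModelConfig(
            h=2, lambda_entropy=50.0, platform_scaling=True, l2_weight=1e-3, seed=0
        )
        prob = _build_problem(data, holdout_genes=[data.panel[0]])
        rng = np.random.default_rng(0)
        raw = _init_raw(prob, cfg, rng)
        _, grads = _loss_and_grad(raw, prob, cfg, epoch=7)
        eps = 1e-6
        for key in raw:
            flat = raw[key].ravel()
            grad = grads[key].ravel()
            for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = _loss_and_grad(raw, prob, cfg, epoch=7)
                flat[i] = orig - eps
                lm, _ = _loss_and_grad(raw, prob, cfg, epoch=7)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6), key


class TestFit:
    def test_structural_invariants_and_restart_contract(self, small_fit):
        model, data, _ = small_fit
        assert_model_valid(model, data.gamma)
        assert len(model.loss_history) == model.config.epochs

    def test_same_seed_is_bitwise_reproducible(self, small_pair):
        data, _ = small_pair
        cfg = sj.ModelConfig(h=2, epochs=50, restarts=2, seed=3)
        a = sj.fit(data, cfg)
        b = sj.fit(data, cfg)
        assert np.array_equal(a.restart_losses, b.restart_losses)
        assert np.array_equal(a.P, b.P)

    def test_loss_decreases_substantially(self, small_fit):
        model, _, _ = small_fit
        assert model.loss_history[-1] < model.loss_history[0]

    def test_holdout_genes_excluded_from_trained_mask(self, small_pair):
        data, _ = small_pair
        held = data.panel[:2]
        cfg = sj.ModelConfig(h=2, epochs=30, restarts=1, seed=0)
        model = sj.fit(data, cfg, holdout_genes=held)
        for g in held:
            assert not model.trained_gene_mask[model.gene_index(g)]
        assert_model_valid(model, data.gamma)

    def test_constant_gene_leaves_assignments_unchanged(self):
        """A gene expressed identically everywhere carries no factor signal,
        so adding it to both slices should not move the fitted assignments."""
        from conftest import standard_pair

        data, _ = standard_pair(seed=6)
        cfg = sj.ModelConfig(h=3, epochs=800, restarts=2, seed=3)
        m1 = sj.fit(data, cfg)

        const_x = sp.csr_matrix(np.ones((data.xenium.n_spots, 1), int))
        xen2 = SRTSlice(
            sp.hstack([data.xenium.counts, const_x]).tocsr(),
            data.xenium.coords,
            data.xenium.gene_names + ["const"],
            data.xenium.spot_ids,
        )
        const_v = sp.csr_matrix(np.asarray((data.gamma.T @ const_x).todense()))
        vis2 = SRTSlice(
            sp.hstack([data.visium.counts, const_v]).tocsr(),
            data.visium.coords,
            data.visium.gene_names + ["const"],
            data.visium.spot_ids,
        )
        universe = (
            data.panel
            + ["const"]
            + [g for g in data.gene_universe if g not in set(data.panel)]
        )
        data2 = sj.align_panels(xen2, vis2, data.gamma, gene_universe=universe)
        m2 = sj.fit(data2, cfg)
        a1, a2 = sj.assign_cell_types(m1), sj.assign_cell_types(m2)
        mapping = sj.match_factors(sj.cosine_similarity_matrix(a1, a2))
        agreement = np.mean([mapping.get(x, -1) == y for x, y in zip(a1, a2)])
        assert agreement >= 0.9
        P2_matched = np.column_stack(
            [m2.P[:, mapping[f]] for f in range(m1.P.shape[1])]
        )
        assert np.abs(m1.P - P2_matched).mean() < 0.15

    def test_nothing_to_train_on_rejected(self):
        data = tiny_pair(
            ax=np.array([[1], [1]]),
            av=np.array([[2]]),
            gamma=np.zeros((2, 1)),
            x_genes=["a"],
            v_genes=["a"],
        )
        cfg = sj.ModelConfig(h=1, epochs=5, restarts=1)
        with pytest.raises(ModelError):
            sj.fit(data, cfg, holdout_genes=["a"])


def manual_model(N, P, Q, M, genes, trained=None):
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    trained = (
        np.ones(Q.shape[1], dtype=bool) if trained is None else np.asarray(trained)
    )
    return sj.FittedModel(
        P=P,
        Q=Q,
        N=np.asarray(N, dtype=float),
        M=sp.csr_matrix(np.asarray(M, dtype=float)),
        phi=np.ones(Q.shape[1]),
        trained_gene_mask=trained,
        gene_universe=list(genes),
        final_loss=0.0,
        loss_history=np.zeros(1),
        restart_losses=np.zeros(1),
        config=sj.ModelConfig(h=P.shape[1], restarts=1),
    )


class TestDownstream:
    def test_impute_rank1_by_hand(self):
        model = manual_model(
            N=[2.0, 3.0], P=[[1.0], [1.0]], Q=[[0.1, 0.9]], M=np.zeros((2, 1)),
            genes=["a", "b"],
        )
        np.testing.assert_allclose(sj.impute(model, ["a"]).ravel(), [0.2, 0.3])

    def test_impute_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(6)
        N = rng.gamma(2, 1, 5)
        P = rng.dirichlet(np.ones(3), 5)
        Q = rng.dirichlet(np.ones(4), 3)
        genes = ["a", "b", "c", "d"]
        model = manual_model(N, P, Q, np.zeros((5, 2)), genes)
        got = sj.impute(model, ["b", "d"])
        for i in range(5):
            for k, j in enumerate([1, 3]):
                expected = sum(N[i] * P[i, t] * Q[t, j] for t in range(3))
                assert got[i, k] == pytest.approx(expected, rel=1e-12)

    def test_impute_trained_genes_equals_reconstruction(self, small_fit):
        model, data, _ = small_fit
        recon = sj.reconstruct_mean(model)
        cols = [model.gene_index(g) for g in data.panel]
        np.testing.assert_array_equal(
            sj.impute(model, data.panel), recon[:, cols]
        )

    def test_impute_unknown_gene_rejected(self, small_fit):
        model, _, _ = small_fit
        with pytest.raises(ModelError, match="nope"):
            sj.impute(model, ["nope"])

    def test_deconvolve_single_cell_spot(self):
        model = manual_model(
            N=[1.0], P=[[0.3, 0.7]], Q=np.full((2, 2), 0.5), M=[[2.0]],
            genes=["a", "b"],
        )
        mix, empty = sj.deconvolve_visium(model)
        np.testing.assert_allclose(mix, [[0.3, 0.7]])
        assert not empty[0]

    def test_deconvolve_empty_spot_flagged(self):
        model = manual_model(
            N=[1.0], P=[[0.5, 0.5]], Q=np.full((2, 2), 0.5),
            M=[[1.0, 0.0]], genes=["a", "b"],
        )
        mix, empty = sj.deconvolve_visium(model)
        assert empty.tolist() == [False, True]
        np.testing.assert_array_equal(mix[1], 0.0)

    def test_deconvolve_rows_sum_to_one(self, small_fit):
        model, _, _ = small_fit
        mix, empty = sj.deconvolve_visium(model)
        np.testing.assert_allclose(mix[~empty].sum(axis=1), 1.0, atol=1e-6)
        # oracle: direct normalization of M^T P
        raw = model.M.T.toarray() @ model.P
        keep = raw.sum(axis=1) > 0
        np.testing.assert_allclose(
            mix[keep], raw[keep] / raw[keep].sum(axis=1, keepdims=True)
        )

    def test_assignment_argmax_and_ties(self):
        model = manual_model(
            N=[1.0, 1.0],
            P=[[0.1, 0.8, 0.1], [0.5, 0.5, 0.0]],
            Q=np.full((3, 2), 0.5),
            M=np.zeros((2, 1)),
            genes=["a", "b"],
        )
        assert sj.assign_cell_types(model).tolist() == [1, 0]


class TestSerialization:
    def test_model_roundtrip(self, small_fit, tmp_path):
        model, _, _ = small_fit
        outdir = str(tmp_path / "model")
        sj.save_model(model, outdir)
        back = sj.load_model(outdir)
        np.testing.assert_allclose(back.P, model.P, atol=1e-12)
        np.testing.assert_allclose(back.Q, model.Q, atol=1e-12)
        np.testing.assert_allclose(back.N, model.N, atol=1e-12)
        assert back.gene_universe == model.gene_universe
        assert back.final_loss == pytest.approx(model.final_loss)
        assert np.array_equal(back.trained_gene_mask, model.trained_gene_mask)
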