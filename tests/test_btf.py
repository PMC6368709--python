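"""Gibbs sampler correctness: conjugate closed forms, limits, determinism."""

import numpy as np
import pytest

from trialtensor import btf, data_model, metrics
from trialtensor.btf import GibbsConfig, LatentState, _CellIndex
from trialtensor.data_model import AugmentedTensor, EntityRegistry, TargetAttributes


def scalar_world(x=1.0, alpha=2.0):
    """1 x 1 x (1+1) tensor with a single observed outcome cell."""
    reg = EntityRegistry(("T0",), ("D0",), ("S0",))
    t = AugmentedTensor(
        reg, np.array([0]), np.array([0]), np.array([1]), np.array([int(x)]),
        has_outcome_slice=True,
    )
    attrs = TargetAttributes(("T0",), np.zeros((1, 1), dtype=np.int8), (("s", "c"),))
    return t, attrs


class TestPredictCP:
    @pytest.mark.parametrize(
        "u, v, e, expected",
        [
            ((1, 1, 1), (1, 1, 1), (1, 1, 1), 3.0),
            ((1, 2), (3, 1), (1, 1), 5.0),
            ((4, -2), (1, 5), (0, 0), 0.0),
        ],
    )
    def test_elementwise_product_sum(self, u, v, e, expected):
        assert btf.predict_cp(np.array(u), np.array(v), np.array(e)) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            btf.predict_cp(np.ones(2), np.ones(3), np.ones(3))


class TestInitState:
    def test_deterministic_under_seed(self, tiny_tensor, tiny_attrs):
        cfg = GibbsConfig(D=2, seed=9)
        s1 = btf.init_state(tiny_tensor, tiny_attrs, cfg)
        s2 = btf.init_state(tiny_tensor, tiny_attrs, cfg)
        assert np.array_equal(s1.U, s2.U) and np.array_equal(s1.E, s2.E)

    def test_dimensions(self, tiny_tensor, tiny_attrs):
        s = btf.init_state(tiny_tensor, tiny_attrs, GibbsConfig(D=1))
        assert s.U.shape == (1, 3) and s.V.shape == (1, 2) and s.E.shape == (1, 3)
        assert s.B.shape == (3, 1) and (s.B == 0).all()

    def test_attribute_row_mismatch_rejected(self, tiny_tensor):
        bad = TargetAttributes(("T0",), np.zeros((1, 1), dtype=np.int8), (("s", "c"),))
        with pytest.raises(ValueError, match="targets"):
            btf.init_state(tiny_tensor, bad, GibbsConfig(D=2))


class TestModeConditional:
    """The full conditional of a factor vector vs its scalar closed form."""

    def test_scalar_posterior_moments(self):
        t, attrs = scalar_world(x=1.0, alpha=2.0)
        cfg = GibbsConfig(D=1, alpha=2.0, seed=0)
        rng = np.random.default_rng(42)
        state = btf.init_state(t, attrs, cfg, rng)
        state.V[:] = 0.7
        state.E[:, 1] = 0.5
        state.mu["target"][:] = 0.3
        state.Lam["target"] = np.array([[1.5]])
        idx = _CellIndex(t)
        q, lam, m, alpha, x = 0.7 * 0.5, 1.5, 0.3, 2.0, 1.0
        prec = lam + alpha * q * q
        mean = (lam * m + alpha * x * q) / prec
        draws = np.array(
            [
                btf.sample_mode_vectors(state, idx, "target", cfg, attrs, rng)[0, 0]
                for _ in range(20_000)
            ]
        )
        se_mean = np.sqrt(1 / prec / len(draws))
        assert abs(draws.mean() - mean) < 4 * se_mean
        se_var = (1 / prec) * np.sqrt(2 / (len(draws) - 1))
        assert abs(draws.var() - 1 / prec) < 4 * se_var

    def test_strong_likelihood_pins_posterior_at_observation(self):
        t, attrs = scalar_world(x=1.0)
        cfg = GibbsConfig(D=1, alpha=1e8, seed=0)
        rng = np.random.default_rng(1)
        state = btf.init_state(t, attrs, cfg, rng)
        state.V[:] = 1.0
        state.E[:, 1] = 1.0
        state.mu["target"][:] = 0.0
        state.Lam["target"] = np.array([[1.0]])
        idx = _CellIndex(t)
        u = btf.sample_mode_vectors(state, idx, "target", cfg, attrs, rng)[0, 0]
        assert abs(u - 1.0) < 1e-3  # conditional mean -> x when alpha -> inf

    def test_entity_without_cells_drawn_from_prior(self):
        reg = EntityRegistry(("T0", "T1"), ("D0",), ("S0",))
        t = AugmentedTensor(
            reg, np.array([0]), np.array([0]), np.array([0]), np.array([1]),
            has_outcome_slice=False,
        )
        attrs = TargetAttributes(
            ("T0", "T1"), np.zeros((2, 1), dtype=np.int8), (("s", "c"),)
        )
        cfg = GibbsConfig(D=1, seed=0)
        rng = np.random.default_rng(3)
        state = btf.init_state(t, attrs, cfg, rng)
        state.mu["target"][:] = 2.0
        state.Lam["target"] = np.array([[4.0]])
        draws = np.array(
            [
                btf.sample_mode_vectors(state, _CellIndex(t), "target", cfg, attrs, rng)[0, 1]
                for _ in range(20_000)
            ]
        )
        assert abs(draws.mean() - 2.0) < 4 * np.sqrt(0.25 / len(draws))
        assert abs(draws.var() - 0.25) < 4 * 0.25 * np.sqrt(2 / len(draws))


class TestHyperparameterConditional:
    def test_large_beta0_pins_mu_at_mu0(self, tiny_tensor, tiny_attrs):
        cfg = GibbsConfig(D=1, mu0=1.5, beta0=1e9, seed=0)
        rng = np.random.default_rng(0)
        state = btf.init_state(tiny_tensor, tiny_attrs, cfg, rng)
        mus = np.array(
            [
                btf.sample_hyperparameters(state, "indication", cfg, tiny_attrs, rng)[0][0]
                for _ in range(200)
            ]
        )
        assert abs(mus.mean() - 1.5) < 1e-3

    def test_posterior_mu_consistent_with_iid_sample(self):
        # many i.i.d. vectors from N(mu*, I): posterior mean of mu near mu*
        rng = np.random.default_rng(5)
        D, n = 2, 4000
        mu_star = np.array([1.0, -2.0])
        reg = EntityRegistry(
            tuple(f"T{i}" for i in range(n)), ("D0",), ("S0",)
        )
        t = AugmentedTensor(
            reg, np.array([0]), np.array([0]), np.array([0]), np.array([1])
        )
        attrs = TargetAttributes(
            reg.targets, np.zeros((n, 1), dtype=np.int8), (("s", "c"),)
        )
        cfg = GibbsConfig(D=D, seed=0)
        state = btf.init_state(t, attrs, cfg, rng)
        state.U = mu_star[:, None] + rng.standard_normal((D, n))
        mus = np.array(
            [
                btf.sample_hyperparameters(state, "target", cfg, attrs, rng)[0]
                for _ in range(300)
            ]
        )
        # posterior sd of mu ~ 1/sqrt(n); allow 4 SE of the MC average
        tol = 4 * (1 / np.sqrt(n)) * (1 + 1 / np.sqrt(300))
        assert np.abs(mus.mean(axis=0) - mu_star).max() < tol

    def test_degenerate_mode_draws_from_hyperprior(self, tiny_tensor, tiny_attrs):
        cfg = GibbsConfig(D=2, seed=0)
        rng = np.random.default_rng(7)
        state = btf.init_state(tiny_tensor, tiny_attrs, cfg, rng)
        state.V = np.empty((2, 0))
        mu, Lam = btf.sample_hyperparameters(state, "indication", cfg, tiny_attrs, rng)
        assert mu.shape == (2,) and Lam.shape == (2, 2)
        assert np.all(np.linalg.eigvalsh(Lam) > 0)


class TestLinkMatrixConditional:
    def test_zero_attributes_fall_back_to_prior(self):
        rng = np.random.default_rng(0)
        M, G, D = 50, 2, 1
        reg = EntityRegistry(tuple(f"T{i}" for i in range(M)), ("D0",), ("S0",))
        attrs = TargetAttributes(
            reg.targets, np.zeros((M, G), dtype=np.int8), (("s", "a"), ("s", "b"))
        )
        cfg = GibbsConfig(D=D, lambda_b=4.0, seed=0)
        state = LatentState(
            U=rng.standard_normal((D, M)),
            V=np.zeros((D, 1)),
            E=np.zeros((D, 1)),
            B=np.zeros((G, D)),
            mu={"target": np.zeros(D)},
            Lam={"target": np.eye(D)},
        )
        draws = np.array(
            [btf.sample_link_matrix(state, attrs, cfg, rng) for _ in range(10_000)]
        )
        # prior N(0, 1/4): mean 0 within 4 SE, variance 1/4
        se = np.sqrt(0.25 / len(draws))
        assert np.abs(draws.mean(axis=0)).max() < 4 * se
        assert np.allclose(draws.var(axis=0), 0.25, rtol=0.1)

    def test_scalar_ridge_posterior_moments(self):
        rng = np.random.default_rng(1)
        M, G, D = 40, 1, 1
        reg_targets = tuple(f"T{i}" for i in range(M))
        F = np.ones((M, G), dtype=np.int8)
        attrs = TargetAttributes(reg_targets, F, (("s", "on"),))
        lam_b, lam_t = 2.0, 1.0
        U = rng.standard_normal((D, M)) + 0.8
        cfg = GibbsConfig(D=D, lambda_b=lam_b, seed=0)
        state = LatentState(
            U=U, V=np.zeros((D, 1)), E=np.zeros((D, 1)), B=np.zeros((G, D)),
            mu={"target": np.zeros(D)}, Lam={"target": np.eye(D) * lam_t},
        )
        prec = lam_t * M + lam_b
        mean = lam_t * U.sum() / prec
        draws = np.array(
            [btf.sample_link_matrix(state, attrs, cfg, rng)[0, 0] for _ in range(20_000)]
        )
        assert abs(draws.mean() - mean) < 4 * np.sqrt(1 / prec / len(draws))
        assert abs(draws.var() - 1 / prec) < 4 * (1 / prec) * np.sqrt(2 / len(draws))

    def test_infinite_shrinkage_sends_b_to_zero(self, tiny_tensor, tiny_attrs):
        cfg = GibbsConfig(D=2, lambda_b=1e12, seed=0)
        rng = np.random.default_rng(2)
        state = btf.init_state(tiny_tensor, tiny_attrs, cfg, rng)
        B = btf.sample_link_matrix(state, tiny_attrs, cfg, rng)
        assert np.abs(B).max() < 1e-4


class TestRunMcmc:
    def test_single_sweep_prediction_is_cp_score(self, tiny_tensor, tiny_attrs):
        cfg = GibbsConfig(D=2, burn_in=0, n_samples=1, seed=4, save_factors=True)
        cells = np.array([[0, 1, 2]])
        s = btf.run_mcmc(tiny_tensor, tiny_attrs, cfg, cells)
        expected = btf.predict_cp(
            s.factor_means["target"][:, 0],
            s.factor_means["indication"][:, 1],
            s.factor_means["evidence"][:, 2],
        )
        assert s.mean[0] == pytest.approx(expected)
        assert s.sd[0] == 0.0

    def test_fixed_seed_reproduces_summary(self, tiny_tensor, tiny_attrs):
        cfg = GibbsConfig(D=2, burn_in=5, n_samples=5, seed=8)
        cells = np.array([[0, 1, 2], [2, 0, 0]])
        s1 = btf.run_mcmc(tiny_tensor, tiny_attrs, cfg, cells)
        s2 = btf.run_mcmc(tiny_tensor, tiny_attrs, cfg, cells)
        assert np.array_equal(s1.samples, s2.samples)

    def test_query_cells_do_not_perturb_the_chain(self, tiny_tensor, tiny_attrs):
        # unobserved cells contribute nothing to any conditional: adding an
        # extra query cell leaves the first cell's trajectory bit-identical
        cfg = GibbsConfig(D=2, burn_in=3, n_samples=4, seed=8)
        s1 = btf.run_mcmc(tiny_tensor, tiny_attrs, cfg, np.array([[0, 1, 2]]))
        s2 = btf.run_mcmc(
            tiny_tensor, tiny_attrs, cfg, np.array([[0, 1, 2], [1, 1, 1]])
        )
        assert np.array_equal(s1.samples[:, 0], s2.samples[:, 0])

    def test_zero_samples_rejected(self, tiny_tensor, tiny_attrs):
        with pytest.raises(ValueError, match="n_samples"):
            btf.run_mcmc(
                tiny_tensor, tiny_attrs, GibbsConfig(D=1, n_samples=0), np.array([[0, 0, 0]])
            )

    def test_out_of_range_query_rejected(self, tiny_tensor, tiny_attrs):
        with pytest.raises(ValueError, match="query"):
            btf.run_mcmc(
                tiny_tensor, tiny_attrs, GibbsConfig(D=1, n_samples=1), np.array([[9, 0, 0]])
            )


class TestSelectRank:
    def test_singleton_grid_returned_without_fitting(self, tiny_tensor, tiny_attrs):
        assert (
            btf.select_rank(tiny_tensor, tiny_attrs, [11], None, GibbsConfig(D=2)) == 11
        )

    def test_empty_grid_rejected(self, tiny_tensor, tiny_attrs):
        with pytest.raises(ValueError, match="grid"):
            btf.select_rank(tiny_tensor, tiny_attrs, [], None, GibbsConfig(D=2))

    def test_true_rank_selected_on_clean_world(self, noise_free_world):
        from trialtensor import benchmark as bench
        from trialtensor.experiments import SYNTH_ALPHA

        w = noise_free_world
        out = w.tensor.outcome_matrix()
        inner = bench.stratified_random_folds(out, 3, seed=2)
        cfg = GibbsConfig(D=3, burn_in=60, n_samples=60, alpha=SYNTH_ALPHA, seed=2)
        assert btf.select_rank(w.tensor, w.attributes, [1, 3], inner, cfg) == 3
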