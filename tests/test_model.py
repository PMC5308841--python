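"""The generative model: distances, ordered-probit probabilities,
likelihood/prior evaluation and their invariances."""

import numpy as np
import pytest
from scipy.stats import norm

import latentconn as lc
from latentconn import model as m
from latentconn import synthetic


def random_params(p, D, K, seed, variant="lsm"):
    return lc.generate_params(p, D, K, seed=seed, variant=variant)


class TestLatentDistance:
    def test_identical_points_have_zero_distance(self):
        Z = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert m.latent_distance(Z)[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        Z = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert m.latent_distance(Z)[0, 1] == pytest.approx(5.0)

    def test_matches_naive_double_loop(self, rng):
        Z = rng.normal(size=(9, 3))
        L = m.latent_distance(Z)
        for i in range(9):
            for j in range(9):
                expect = np.sqrt(((Z[i] - Z[j]) ** 2).sum())
                assert L[i, j] == pytest.approx(expect, abs=1e-12)

    def test_metric_properties(self, rng):
        Z = rng.normal(size=(8, 2))
        L = m.latent_distance(Z)
        assert np.allclose(L, L.T)
        assert np.all(np.diag(L) == 0)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert L[i, j] <= L[i, k] + L[k, j] + 1e-12

    def test_zero_dimensional_embedding(self):
        L = m.latent_distance(np.zeros((4, 0)))
        assert np.all(L == 0)


class TestEigenDistance:
    def test_unit_vector_self_product(self):
        Z = np.array([[1.0, 0.0], [1.0, 0.0]])
        L = m.eigen_distance(Z, np.ones(2))
        assert L[0, 1] == pytest.approx(-1.0)

    def test_orthogonal_vectors(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert m.eigen_distance(Z, np.ones(2))[0, 1] == pytest.approx(0.0)

    def test_identity_spectrum_relates_to_euclidean_distance(self, rng):
        # -z_i.z_j = (||z_i - z_j||^2 - ||z_i||^2 - ||z_j||^2) / 2
        Z = rng.normal(size=(6, 3))
        bilinear = m.eigen_distance(Z, np.ones(3))
        sq = m.latent_distance(Z) ** 2
        norms = (Z**2).sum(axis=1)
        expect = (sq - norms[:, None] - norms[None, :]) / 2
        np.testing.assert_allclose(bilinear, expect, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(lc.ValidationError):
            m.eigen_distance(np.zeros((3, 2)), np.ones(3))


class TestClassProbs:
    def test_binary_symmetric_point(self):
        f = m.class_probs(0.0, 0.0, 0.0, np.array([0.0]), 1.0)
        np.testing.assert_allclose(f, [0.5, 0.5])

    def test_infinite_distance_limit_is_absent(self):
        f = m.class_probs(1e3, 0.0, 0.0, np.array([0.0]), 1.0)
        assert f[0] == pytest.approx(1.0, abs=1e-12)

    def test_four_class_interval_masses(self):
        # cutpoints [1,2,3] at distance 2: interval masses are the
        # standard normal CDF differences at -1, 0, 1
        f = m.class_probs(2.0, 0.0, 0.0, np.array([1.0, 2.0, 3.0]), 1.0)
        phi = norm.cdf([-1.0, 0.0, 1.0])
        # weight 3 (strongest class) takes the innermost interval
        expect = [1 - phi[2], phi[2] - phi[1], phi[1] - phi[0], phi[0]]
        np.testing.assert_allclose(f, expect, atol=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(lc.ValidationError):
            m.class_probs(np.inf, 0.0, 0.0, np.array([0.0]), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.integers(2, 6)
        b = np.sort(rng.normal(0, 2, K - 1))
        b += np.arange(K - 1) * 1e-3  # ensure strict ordering
        sigma = float(rng.uniform(0.2, 2.0))
        l = float(rng.uniform(0, 4))
        d, e = rng.normal(0, 0.5, 2)
        f = m.class_probs(l, d, e, b, sigma)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(f >= 0) and np.all(f <= 1)
        k = np.arange(K)
        ew = f @ k
        h = 1e-4
        assert m.class_probs(l + h, d, e, b, sigma) @ k < ew
        assert m.class_probs(l, d + h, e, b, sigma) @ k > ew
        assert m.class_probs(l, d, e + h, b, sigma) @ k > ew


class TestLogLikelihood:
    def test_empty_mask_contributes_nothing(self):
        params = random_params(4, 2, 3, seed=0)
        conn = lc.OrdinalConnectome(
            list("abcd"), np.zeros((4, 4), int),
            np.zeros((4, 4), bool), 3,
        )
        assert m.log_likelihood(params, conn) == 0.0

    def test_single_edge_is_one_log_term(self):
        # b = Phi^-1(0.8) makes the present-class probability exactly 0.8
        params = m.ModelParams(
            embedding=m.LatentEmbedding(np.zeros((2, 1))),
            cutpoints=m.Cutpoints(np.array([norm.ppf(0.8)])),
            sigma=1.0,
            effects=m.RandomEffects(np.zeros(2), np.zeros(2)),
        )
        conn = lc.OrdinalConnectome(
            ["a", "b"], np.array([[0, 1], [0, 0]]),
            np.array([[False, True], [False, False]]), 2,
        )
        assert m.log_likelihood(params, conn) == pytest.approx(np.log(0.8))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_edge_loop_oracle(self, seed):
        params = random_params(6, 2, 4, seed=seed)
        inst = synthetic.generate_connectome(params, seed=seed + 50)
        data = inst.data
        L = m.latent_distance(params.Z)
        expect = 0.0
        for i in range(6):
            for j in range(6):
                if not data.observed_mask[i, j]:
                    continue
                f = m.class_probs(
                    L[i, j], params.delta[i], params.eps[j],
                    params.b, params.sigma,
                )
                expect += np.log(f[data.weights[i, j]])
        assert m.log_likelihood(params, data) == pytest.approx(
            expect, abs=1e-12
        )

    def test_out_of_range_weight_rejected(self):
        params = random_params(3, 1, 2, seed=1)
        conn = lc.OrdinalConnectome(
            list("abc"), np.zeros((3, 3), int),
            ~np.eye(3, dtype=bool), 2,
        )
        conn.weights[0, 1] = 5  # corrupt after validation
        conn.observed_mask[0, 1] = True
        with pytest.raises(lc.ValidationError):
            m.log_likelihood(params, conn)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(8, 3, 4, seed=seed)
        inst = synthetic.generate_connectome(params, seed=seed + 60)
        base = m.log_likelihood(params, inst.data)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(size=3)
        moved = m.ModelParams(
            embedding=m.LatentEmbedding(params.Z @ Q + shift),
            cutpoints=params.cutpoints,
            sigma=params.sigma,
            effects=params.effects,
        )
        assert m.log_likelihood(moved, inst.data) == pytest.approx(
            base, abs=1e-10
        )

    @pytest.mark.parametrize("c", [0.3, 2.0, 7.5])
    def test_invariant_under_joint_rescaling(self, c):
        # (Z, b, delta, eps, sigma) -> c * (...) leaves the model
        # unchanged: the non-identifiability the priors pin down
        params = random_params(8, 2, 4, seed=3)
        inst = synthetic.generate_connectome(params, seed=63)
        base = m.log_likelihood(params, inst.data)
        scaled = m.ModelParams(
            embedding=m.LatentEmbedding(c * params.Z),
            cutpoints=m.Cutpoints(c * params.b),
            sigma=c * params.sigma,
            effects=m.RandomEffects(c * params.delta, c * params.eps),
        )
        assert m.log_likelihood(scaled, inst.data) == pytest.approx(
            base, abs=1e-9
        )

    def test_fusion_with_identical_modalities_doubles_likelihood(self):
        params = random_params(7, 2, 4, seed=4)
        inst = synthetic.generate_connectome(params, seed=64)
        single = m.log_likelihood(params, inst.data)
        double = m.log_likelihood(
            params, inst.data, second_modality=inst.data
        )
        assert double == pytest.approx(2 * single, abs=1e-10)


class TestClassProbMatrix:
    def test_rows_normalized_everywhere(self):
        params = random_params(10, 2, 4, seed=9)
        f = m.class_prob_matrix(params).f
        np.testing.assert_allclose(f.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(f >= 0)

    def test_zero_dim_variant_is_distance_free(self):
        params = random_params(5, 0, 3, seed=2)
        f = m.class_prob_matrix(params, "zero_dim").f
        # without effects variation, rows would be constant; here only
        # delta/eps differ, so edges sharing (i, j) effects agree
        assert f.shape == (5, 5, 3)


class TestLogPrior:
    def test_analytic_value_at_prior_mode(self):
        # K = 2 (no increment terms), everything at the mode
        p, D = 3, 2
        params = m.ModelParams(
            embedding=m.LatentEmbedding(np.zeros((p, D))),
            cutpoints=m.Cutpoints(np.array([0.0])),
            sigma=1.0,
            effects=m.RandomEffects(np.zeros(p), np.zeros(p)),
        )
        hyper = m.Hyperparams()
        expect = (
            p * D * norm.logpdf(0.0, scale=hyper.z_scale)
            + norm.logpdf(0.0, scale=hyper.cut_loc_scale)
            + 2 * p * norm.logpdf(0.0, scale=hyper.effect_scale)
        )
        assert m.log_prior(params, hyper) == pytest.approx(expect, abs=1e-12)

    def test_clamped_effects_contribute_no_terms(self):
        p = 4
        base = m.ModelParams(
            embedding=m.LatentEmbedding(np.zeros((p, 1))),
            cutpoints=m.Cutpoints(np.array([0.0])),
            sigma=1.0,
            effects=m.RandomEffects(np.zeros(p), np.zeros(p)),
        )
        clamped = m.ModelParams(
            embedding=m.LatentEmbedding(np.zeros((p, 1))),
            cutpoints=m.Cutpoints(np.array([0.0])),
            sigma=1.0,
            effects=m.RandomEffects(
                np.zeros(p), np.zeros(p),
                active_delta=np.zeros(p, dtype=bool),
                active_eps=np.ones(p, dtype=bool),
            ),
        )
        hyper = m.Hyperparams()
        diff = m.log_prior(base, hyper) - m.log_prior(clamped, hyper)
        assert diff == pytest.approx(
            p * norm.logpdf(0.0, scale=hyper.effect_scale)
        )

    def test_out_of_support_is_minus_infinity(self):
        params = random_params(3, 1, 4, seed=0)
        hyper = m.Hyperparams()
        params.sigma = -1.0  # corrupt past construction-time validation
        assert m.log_prior(params, hyper) == -np.inf
        params.sigma = 1.0
        params.cutpoints.b = np.array([2.0, 1.0, 0.0])
        assert m.log_prior(params, hyper) == -np.inf

    def test_log_posterior_is_sum_of_parts(self):
        params = random_params(6, 2, 4, seed=8)
        inst = synthetic.generate_connectome(params, seed=68)
        hyper = m.Hyperparams()
        assert m.log_posterior(params, inst.data, hyper) == pytest.approx(
            m.log_prior(params, hyper)
            + m.log_likelihood(params, inst.data)
        )

    def test_log_posterior_empty_mask_equals_prior(self):
        params = random_params(4, 2, 3, seed=8)
        conn = lc.OrdinalConnectome(
            list("abcd"), np.zeros((4, 4), int), np.zeros((4, 4), bool), 3
        )
        hyper = m.Hyperparams()
        assert m.log_posterior(params, conn, hyper) == m.log_prior(
            params, hyper
        )
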