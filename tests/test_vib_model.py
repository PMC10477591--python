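import numpy as np
import pytest

from mvcvib import (
    GaussianPosterior,
    ModelConfig,
    decode,
    encode_view,
    init_params,
    kl_to_standard_normal,
    load_checkpoint,
    loss_and_grads,
    mvcvib_loss,
    poe_combine,
    poe_combine_prior,
    predict_proba,
    reparameterize,
    save_checkpoint,
    AbundanceTable,
)
from mvcvib.vib_model import _grid_side
from mvcvib.views import MultiViewInput

from oracles import grid_poe_moments, monte_carlo_kl


def _toy_batch(config, rng, n=4, d_abund=10, d_dist=5):
    X = rng.dirichlet(np.ones(d_abund), size=n)
    D = rng.random((n, d_dist))
    views = MultiViewInput((X, D), ("abundance", "distance"))
    params = init_params(config, {"abundance": d_abund, "distance": d_dist}, rng)
    y = np.array([0, 1, 0, 1][:n])
    return views, params, y


class TestPoECombine:
    def test_empty_product_is_the_prior(self):
        p = poe_combine([], latent_dim=3)
        np.testing.assert_array_equal(p.mu, np.zeros(3))
        np.testing.assert_array_equal(p.sigma, np.ones(3))
        q = poe_combine_prior(3)
        np.testing.assert_array_equal(p.mu, q.mu)

    def test_single_standard_expert(self):
        # N(1,1) times the prior: precision 2, mean 1/2, variance 1/2
        p = poe_combine([GaussianPosterior([1.0], [1.0])])
        assert p.mu[0] == pytest.approx(0.5, abs=1e-12)
        assert p.sigma[0] ** 2 == pytest.approx(0.5, abs=1e-12)

    def test_two_experts_with_prior(self):
        # N(1,1) and N(-1,4): precisions 1 + 1 + 0.25 = 2.25
        p = poe_combine([GaussianPosterior([1.0], [1.0]),
                         GaussianPosterior([-1.0], [2.0])])
        assert p.mu[0] == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert p.sigma[0] ** 2 == pytest.approx(4.0 / 9.0, abs=1e-12)

    def test_matches_grid_density_product(self, rng):
        for _ in range(20):
            n_exp = rng.integers(1, 4)
            mus = rng.uniform(-2, 2, n_exp)
            sigmas = rng.uniform(0.3, 2.0, n_exp)
            combined = poe_combine(
                [GaussianPosterior([m], [s]) for m, s in zip(mus, sigmas)])
            mean, var = grid_poe_moments(mus, sigmas)
            assert combined.mu[0] == pytest.approx(mean, abs=1e-6)
            assert combined.sigma[0] ** 2 == pytest.approx(var, abs=1e-6)

    def test_variance_never_exceeds_any_expert_or_prior(self, rng):
        experts = [GaussianPosterior(rng.normal(size=6),
                                     rng.uniform(0.1, 3.0, 6))
                   for _ in range(4)]
        combined = poe_combine(experts)
        var = combined.sigma ** 2
        assert np.all(var <= 1.0 + 1e-12)  # never wider than the prior
        for e in experts:
            assert np.all(var <= e.sigma ** 2 + 1e-12)

    def test_mismatched_dimension_errors(self):
        with pytest.raises(ValueError, match="dimension"):
            poe_combine([GaussianPosterior([0.0], [1.0]),
                         GaussianPosterior([0.0, 0.0], [1.0, 1.0])])


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        p = GaussianPosterior([2.0, -1.0], [0.5, 2.0])
        np.testing.assert_array_equal(reparameterize(p, np.zeros(2)), p.mu)

    def test_elementwise_arithmetic(self):
        p = GaussianPosterior([2.0, -1.0], [0.5, 2.0])
        np.testing.assert_allclose(reparameterize(p, np.ones(2)), [2.5, 1.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            reparameterize(GaussianPosterior([0.0], [1.0]), np.zeros(2))


class TestDecode:
    def test_zero_weights_give_half(self, rng):
        cfg = ModelConfig(latent_dim=2, hidden_sizes=(4, 3, 3))
        params = init_params(cfg, {"abundance": 5}, rng)
        params["decoder.w"].data[:] = 0.0
        params["decoder.b"].data[:] = 0.0
        assert decode(rng.normal(size=2), params) == pytest.approx(0.5)

    def test_scalar_sigmoid_value(self, rng):
        cfg = ModelConfig(latent_dim=2, hidden_sizes=(4, 3, 3))
        params = init_params(cfg, {"abundance": 5}, rng)
        params["decoder.w"].data[:, 0] = [1.0, 1.0]
        params["decoder.b"].data[:] = -1.0
        # w'u + b = 1 -> sigmoid(1)
        assert decode(np.array([1.0, 1.0]), params) == pytest.approx(
            0.731059, abs=1e-6)

    def test_output_strictly_inside_unit_interval(self, rng):
        cfg = ModelConfig(latent_dim=3, hidden_sizes=(4, 3, 3))
        params = init_params(cfg, {"abundance": 5}, rng)
        # moderate magnitudes keep sigmoid away from float64 saturation
        for u in [np.full(3, 10.0), np.full(3, -10.0), rng.normal(size=3)]:
            p = decode(u, params)
            assert 0.0 < p < 1.0


class TestKL:
    def test_standard_normal_has_zero_kl(self):
        assert kl_to_standard_normal(poe_combine_prior(7)) == pytest.approx(0.0)

    def test_unit_shift_gives_half(self):
        assert kl_to_standard_normal(
            GaussianPosterior([1.0], [1.0])) == pytest.approx(0.5)

    def test_nonnegative_and_matches_monte_carlo(self, rng):
        for _ in range(5):
            k = int(rng.integers(1, 5))
            mu = rng.normal(0, 1.5, k)
            sigma = rng.uniform(0.3, 2.5, k)
            closed = kl_to_standard_normal(GaussianPosterior(mu, sigma))
            assert closed >= 0.0
            estimate, se = monte_carlo_kl(mu, sigma, 200_000, rng)
            assert abs(closed - estimate) <= 3.0 * se


class TestEncoder:
    def test_eval_mode_is_deterministic(self, small_config, rng):
        _, params, _ = _toy_batch(small_config, rng)
        x = rng.dirichlet(np.ones(10))
        a = encode_view(x, "abundance", params, small_config, training=False)
        b = encode_view(x, "abundance", params, small_config, training=False)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_zero_parameters_give_standard_posterior(self, small_config, rng):
        _, params, _ = _toy_batch(small_config, rng)
        for p in params.values():
            p.data[:] = 0.0
        post = encode_view(rng.random(10), "abundance", params, small_config)
        np.testing.assert_allclose(post.mu, 0.0, atol=1e-15)
        np.testing.assert_allclose(post.sigma, 1.0, atol=1e-15)

    def test_grid_padding_dimension(self):
        # a 10-vector fits a 4×4 grid: ceil(sqrt(10)) = 4
        assert _grid_side(10) == 4
        assert _grid_side(16) == 4
        assert _grid_side(17) == 5

    def test_dropout_requires_noise_source(self, rng):
        cfg = ModelConfig(latent_dim=4, hidden_sizes=(8, 6, 6), dropout_p=0.2)
        params = init_params(cfg, {"abundance": 10}, rng)
        with pytest.raises(ValueError, match="rng"):
            encode_view(rng.random(10), "abundance", params, cfg, training=True)


class TestLoss:
    def test_beta_zero_total_equals_nll(self, rng):
        cfg = ModelConfig(latent_dim=4, hidden_sizes=(8, 6, 6),
                          dropout_p=0.0, beta=0.0)
        views, params, y = _toy_batch(cfg, rng)
        eps = rng.standard_normal((4, 4))
        total, nll, kl = mvcvib_loss(views, y, params, cfg, eps)
        assert total == nll
        assert kl > 0.0

    def test_fixed_inputs_are_bit_deterministic(self, small_config, rng):
        views, params, y = _toy_batch(small_config, rng)
        eps = rng.standard_normal((4, small_config.latent_dim))
        a = mvcvib_loss(views, y, params, small_config, eps)
        b = mvcvib_loss(views, y, params, small_config, eps)
        assert a == b

    def test_posterior_mean_pass_is_deterministic(self, small_config, rng):
        views, params, _ = _toy_batch(small_config, rng)
        np.testing.assert_array_equal(
            predict_proba(views, params, small_config),
            predict_proba(views, params, small_config))

    def test_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(latent_dim=3, hidden_sizes=(6, 5, 5),
                          conv_channels=2, dropout_p=0.0, beta=1e-3)
        views, params, y = _toy_batch(cfg, rng, d_abund=9, d_dist=4)
        eps = rng.standard_normal((4, 3))
        _, grads = loss_and_grads(views, y, params, cfg, eps)
        for name, p in params.items():
            flat = p.data.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size),
                                  replace=False):
                h = 1e-6
                orig = flat[idx]
                flat[idx] = orig + h
                up = mvcvib_loss(views, y, params, cfg, eps)[0]
                flat[idx] = orig - h
                down = mvcvib_loss(views, y, params, cfg, eps)[0]
                flat[idx] = orig
                fd = (up - down) / (2 * h)
                bp = grads[name].ravel()[idx]
                assert abs(fd - bp) <= 1e-4 * max(1.0, abs(fd)), \
                    f"{name}[{idx}]: fd={fd} bp={bp}"


class TestCheckpoint:
    def test_round_trip_restores_identical_predictions(self, small_config,
                                                       rng, tmp_path):
        views, params, _ = _toy_batch(small_config, rng)
        ref = AbundanceTable(tuple(f"s{i}" for i in range(4)),
                             tuple(f"f{i}" for i in range(10)),
                             rng.dirichlet(np.ones(10), size=4))
        before = predict_proba(views, params, small_config)
        save_checkpoint(tmp_path / "ckpt", params, small_config, ref)
        params2, config2, ref2 = load_checkpoint(tmp_path / "ckpt")
        assert config2 == small_config
        assert ref2.sample_ids == ref.sample_ids
        np.testing.assert_array_equal(ref2.values, ref.values)
        after = predict_proba(views, params2, config2)
        np.testing.assert_array_equal(before, after)
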