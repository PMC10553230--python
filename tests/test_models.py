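"""The six VAE losses: closed forms, reduction identities, estimators."""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from vaebench.models import (ACTIVATIONS, INIT_SCHEMES,
                             ModelSpec, VAEModel, beta_vae_loss, btcvae_loss,
                             catvae_loss, categorical_kl_from_probs,
                             dip_penalty_from_cov, dipvae_loss, gaussian_kl,
                             gumbel_softmax_sample, init_weights, iwae_loss,
                             mse_reconstruction, reparameterize,
                             single_draw_elbo, vanilla_loss,
                             xavier_uniform_bound)


class TestInitWeights:
    def test_uniform01_support(self):
        (w,) = init_weights([(50, 40)], "uniform01", seed=0)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_normal01_moments(self):
        (w,) = init_weights([(500, 200)], "normal01", seed=0)  # 1e5 draws
        assert abs(w.mean()) < 0.02
        assert abs(w.std() - 1.0) < 0.02

    def test_xavier_uniform_bound_512(self):
        bound = xavier_uniform_bound(512, 512)
        assert bound == pytest.approx(math.sqrt(6.0 / 1024.0))
        (w,) = init_weights([(512, 512)], "xavier_uniform", seed=1)
        assert np.abs(w).max() <= bound

    def test_deterministic_given_seed(self):
        a = init_weights([(10, 10)], "xavier_normal", seed=3)
        b = init_weights([(10, 10)], "xavier_normal", seed=3)
        assert np.array_equal(a[0], b[0])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            init_weights([(4, 4)], "glorot", seed=0)


class TestGaussianKL:
    def test_standard_normal_posterior_is_zero(self):
        assert gaussian_kl(np.zeros(3), np.zeros(3)) == 0.0

    def test_mean_shift_closed_form(self):
        assert gaussian_kl(np.array([2.0, 0.0]), np.zeros(2)) == pytest.approx(2.0)

    def test_matches_numerical_quadrature(self):
        mu, lv = 0.3, -0.5
        sd = math.exp(lv / 2)

        def integrand(z):
            q = norm.pdf(z, mu, sd)
            return q * (norm.logpdf(z, mu, sd) - norm.logpdf(z, 0, 1))

        expected, _ = quad(integrand, -10, 10)
        assert gaussian_kl(np.array([mu]), np.array([lv])) == pytest.approx(expected, abs=1e-6)

    def test_batched_rows(self):
        mu = np.array([[2.0, 0.0], [0.0, 0.0]])
        lv = np.zeros((2, 2))
        assert np.allclose(gaussian_kl(mu, lv), [2.0, 0.0])


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        mu = np.array([1.0, -2.0])
        assert np.array_equal(reparameterize(mu, np.zeros(2), np.zeros(2)), mu)

    def test_unit_variance_shifts_by_noise(self):
        mu, n = np.array([1.0]), np.array([0.7])
        assert reparameterize(mu, np.zeros(1), n) == pytest.approx(1.7)

    def test_empirical_covariance(self, rng):
        lv = np.array([0.4, -0.6])
        noise = rng.standard_normal((100_000, 2))
        z = reparameterize(np.zeros(2), lv, noise)
        emp = np.var(z, axis=0)
        assert np.allclose(emp, np.exp(lv), rtol=0.02)


class TestVanillaAndBeta:
    def test_perfect_fit_prior_posterior_zero(self):
        x = np.ones((1, 2))
        lb = vanilla_loss(x, x, np.zeros((1, 2)), np.zeros((1, 2)))
        assert lb.total == 0.0

    def test_summed_squared_error(self):
        x = np.array([[1.0, 1.0]])
        lb = vanilla_loss(x, np.zeros((1, 2)), np.zeros((1, 2)), np.zeros((1, 2)))
        assert lb.total == pytest.approx(2.0)

    def test_batch_mean_of_per_sample_totals(self):
        # per-sample summed squared errors 2 and 4 -> batch mean 3
        x = np.array([[1.0, 1.0], [2.0, 0.0]])
        lb = vanilla_loss(x, np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        assert lb.total == pytest.approx(3.0)

    def test_beta_one_reduces_to_vanilla_bit_exact(self, rng):
        x = rng.standard_normal((4, 3))
        xh = rng.standard_normal((4, 3))
        mu = rng.standard_normal((4, 2))
        lv = rng.standard_normal((4, 2))
        v = vanilla_loss(x, xh, mu, lv, kl_weight=0.37)
        b = beta_vae_loss(x, xh, mu, lv, beta=1.0, kl_weight=0.37)
        assert v.total == b.total and v.kl == b.kl and v.reconstruction == b.reconstruction

    def test_beta_arithmetic(self):
        # recon 1 (single sample, error (1,0)), kl 2 (mu (2,0)), beta 4 -> 9
        x = np.array([[1.0, 0.0]])
        lb = beta_vae_loss(x, np.zeros((1, 2)), np.array([[2.0, 0.0]]),
                           np.zeros((1, 2)), beta=4.0)
        assert lb.total == pytest.approx(9.0)

    def test_beta_zero_removes_kl(self, rng):
        x, xh = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        mu, lv = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        lb = beta_vae_loss(x, xh, mu, lv, beta=0.0)
        assert lb.total == lb.reconstruction


class TestBtcvae:
    def test_single_latent_has_zero_total_correlation(self, rng):
        mu = rng.standard_normal((6, 1))
        lv = rng.standard_normal((6, 1)) * 0.1
        z = reparameterize(mu, lv, rng.standard_normal((6, 1)))
        x = rng.standard_normal((6, 4))
        lb = btcvae_loss(x, x, mu, lv, z, alpha=1, beta=1, gamma=1, dataset_size=6)
        assert lb.tc_term == 0.0

    def test_zero_weights_leave_reconstruction(self, rng):
        mu = rng.standard_normal((5, 3))
        lv = rng.standard_normal((5, 3)) * 0.1
        z = reparameterize(mu, lv, rng.standard_normal((5, 3)))
        x, xh = rng.standard_normal((5, 4)), rng.standard_normal((5, 4))
        lb = btcvae_loss(x, xh, mu, lv, z, alpha=0, beta=0, gamma=0, dataset_size=5)
        assert lb.total == lb.reconstruction

    def test_batch_of_one_rejected(self, rng):
        mu = rng.standard_normal((1, 2))
        with pytest.raises(ValueError, match="batch"):
            btcvae_loss(np.zeros((1, 3)), np.zeros((1, 3)), mu, np.zeros((1, 2)),
                        mu, alpha=1, beta=1, gamma=1, dataset_size=10)

    def test_decomposition_matches_analytic_kl(self, rng):
        """mi + tc + dim_kl at unit weights estimates the batch-mean KL;
        over 200 z-resamples the average agrees within 3 standard errors."""
        B, D = 10, 3
        mu = rng.standard_normal((B, D))
        lv = rng.standard_normal((B, D)) * 0.3
        x = rng.standard_normal((B, 4))
        analytic = float(np.mean(gaussian_kl(mu, lv)))
        draws = []
        for _ in range(200):
            z = reparameterize(mu, lv, rng.standard_normal((B, D)))
            lb = btcvae_loss(x, x, mu, lv, z, alpha=1, beta=1, gamma=1, dataset_size=B)
            draws.append(lb.mi_term + lb.tc_term + lb.dim_kl_term)
        draws = np.array(draws)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - analytic) <= 3 * se


class TestDipVae:
    def test_identity_covariance_gives_zero_penalty(self):
        # identical posterior means (zero covariance) + unit encoder variance
        mu = np.tile([[1.0, -2.0]], (4, 1))
        lv = np.zeros((4, 2))
        x = np.zeros((4, 3))
        lb = dipvae_loss(x, x, mu, lv, lambda_d=1.0, lambda_od=1.0)
        assert lb.dip_penalty == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_penalty(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert dip_penalty_from_cov(cov, lambda_d=1.0, lambda_od=1.0) == pytest.approx(0.5)

    def test_zero_lambdas_reduce_to_vanilla(self, rng):
        x, xh = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        mu, lv = rng.standard_normal((4, 2)), rng.standard_normal((4, 2))
        d = dipvae_loss(x, xh, mu, lv, lambda_d=0.0, lambda_od=0.0)
        v = vanilla_loss(x, xh, mu, lv)
        assert d.total == v.total

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError, match="batch"):
            dipvae_loss(np.zeros((1, 2)), np.zeros((1, 2)), np.zeros((1, 2)),
                        np.zeros((1, 2)), 1.0, 1.0)


def _toy_decoder(rng, d_z, d_x):
    A = rng.standard_normal((d_z, d_x))

    def decoder(z):
        return z @ A

    return decoder


class TestIwae:
    def test_k1_equals_single_draw_elbo(self, rng):
        B, D, G = 3, 2, 4
        dec = _toy_decoder(rng, D, G)
        x = rng.standard_normal((B, G))
        mu, lv = rng.standard_normal((B, D)), rng.standard_normal((B, D)) * 0.3
        noise = rng.standard_normal((B, D))
        loss_k1 = iwae_loss(x, dec, mu, lv, K=1, noise_draws=noise[:, None, :])
        elbo = single_draw_elbo(x, dec, mu, lv, noise)
        assert loss_k1 == pytest.approx(elbo, abs=1e-12)

    def test_duplicated_draws_collapse_to_k1(self, rng):
        B, D, G = 3, 2, 4
        dec = _toy_decoder(rng, D, G)
        x = rng.standard_normal((B, G))
        mu, lv = rng.standard_normal((B, D)), rng.standard_normal((B, D)) * 0.3
        noise = rng.standard_normal((B, D))
        dup = np.repeat(noise[:, None, :], 5, axis=1)
        loss_dup = iwae_loss(x, dec, mu, lv, K=5, noise_draws=dup)
        loss_k1 = iwae_loss(x, dec, mu, lv, K=1, noise_draws=noise[:, None, :])
        assert loss_dup == pytest.approx(loss_k1, abs=1e-9)

    def test_bound_tightens_with_k(self, rng):
        """Monte-Carlo: the K=5 bound is no looser than K=1 (within 3 SE)."""
        B, D, G = 4, 2, 3
        dec = _toy_decoder(rng, D, G)
        x = rng.standard_normal((B, G))
        mu, lv = rng.standard_normal((B, D)), rng.standard_normal((B, D)) * 0.3
        diffs = []
        for _ in range(500):
            n5 = rng.standard_normal((B, 5, D))
            b5 = -iwae_loss(x, dec, mu, lv, K=5, noise_draws=n5)
            b1 = -iwae_loss(x, dec, mu, lv, K=1, noise_draws=n5[:, :1, :])
            diffs.append(b5 - b1)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert diffs.mean() >= -3 * se


class TestGumbelSoftmax:
    def test_rows_sum_to_one(self, rng):
        logits = rng.standard_normal((5, 3, 4))
        u = rng.random((5, 3, 4))
        y = gumbel_softmax_sample(logits, 0.7, u)
        assert np.allclose(y.sum(axis=-1), 1.0, atol=1e-6)

    def test_low_temperature_approaches_one_hot(self, rng):
        logits = np.array([[5.0, 0.0, 0.0]])
        u = np.full((1, 3), 0.5)
        y = gumbel_softmax_sample(logits, 0.01, u)
        assert np.max(np.abs(y - np.array([[1.0, 0.0, 0.0]]))) < 1e-3

    def test_argmax_frequencies_follow_softmax(self, rng):
        logits = np.array([0.5, -0.3, 1.1, 0.0])
        p = np.exp(logits) / np.exp(logits).sum()
        u = np.clip(rng.random((100_000, 4)), 1e-12, 1 - 1e-12)
        y = gumbel_softmax_sample(logits[None, :], 0.5, u)
        freq = np.bincount(np.argmax(y, axis=-1), minlength=4) / 100_000
        assert np.allclose(freq, p, atol=0.02)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            gumbel_softmax_sample(np.zeros((1, 2)), 0.0, np.full((1, 2), 0.5))


class TestCatVae:
    def test_uniform_posterior_zero_kl(self):
        logits = np.zeros((2, 3, 4))
        x = np.zeros((2, 5))
        lb = catvae_loss(x, x, logits)
        assert lb.kl == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_uniform_is_log_c(self):
        assert categorical_kl_from_probs([1.0, 0.0]) == pytest.approx(math.log(2))

    def test_matches_direct_summation(self, rng):
        p = rng.dirichlet(np.ones(4))
        direct = float(np.sum(p * np.log(p * 4)))
        assert categorical_kl_from_probs(p) == pytest.approx(direct)
        # and through the logits path
        logits = np.log(p)[None, None, :]
        lb = catvae_loss(np.zeros((1, 2)), np.zeros((1, 2)), logits)
        assert lb.kl == pytest.approx(direct, abs=1e-9)


class TestModelInvariants:
    @pytest.mark.parametrize("init,act", list(itertools.product(INIT_SCHEMES, ACTIVATIONS)))
    def test_finite_gradients_at_initialization(self, init, act, rng):
        spec = ModelSpec(variant="vanilla", input_dim=6, latent_dim=3,
                         activation=act, init_scheme=init, hidden_dim=16)
        model = VAEModel(spec, seed=0)
        x = rng.standard_normal((8, 6))
        lb = model.loss(x, np.random.default_rng(0), dataset_size=8)
        assert np.isfinite(lb.total.value)
        lb.total.backward()
        assert model.grads_finite()

    @pytest.mark.parametrize("variant", ["vanilla", "beta_vae", "beta_tcvae",
                                         "dip_vae", "iwae", "cat_vae"])
    def test_each_variant_loss_finite_and_differentiable(self, variant, rng):
        spec = ModelSpec(variant=variant, input_dim=6, latent_dim=3, hidden_dim=16)
        model = VAEModel(spec, seed=1)
        x = rng.standard_normal((8, 6))
        lb = model.loss(x, np.random.default_rng(1), dataset_size=8)
        assert np.isfinite(lb.total.value)
        lb.total.backward()
        assert model.grads_finite()
        grads = [t.grad for t in model.params.values() if t.grad is not None]
        assert any(np.abs(g).max() > 0 for g in grads)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        spec = ModelSpec(variant="vanilla", input_dim=5, latent_dim=2, hidden_dim=8)
        model = VAEModel(spec, seed=4)
        x = rng.standard_normal((3, 5))
        before = model.embed(x)
        path = tmp_path / "ckpt.tsv"
        model.save(path)
        loaded = VAEModel.load(path, spec)
        assert np.allclose(loaded.embed(x), before, atol=1e-12)

    def test_reconstruction_is_sum_over_genes_mean_over_batch(self, rng):
        x = rng.standard_normal((6, 4))
        xh = rng.standard_normal((6, 4))
        expected = np.mean(np.sum((x - xh) ** 2, axis=1))
        assert mse_reconstruction(x, xh) == pytest.approx(expected)
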