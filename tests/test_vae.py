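"""VAE classifier: posterior construction, ELBO oracles, training."""

import numpy as np
import pytest
from scipy import stats

from mivae import (
    ElboReport,
    VaeConfig,
    elbo,
    encode,
    finetune,
    init_vae,
    pretrain_layerwise,
    reparameterize,
    vae_predict,
)
from mivae._nn import Dense, softplus
from mivae.vae import GaussianVae, elbo_and_grads, gaussian_kl, train_stage

from conftest import fast_vae_config


def toy_model(seed=3, scale=0.3):
    cfg = VaeConfig(
        input_dim=6, hidden_dims=(4, 3, 2, 3, 4), dtype="float64",
        seed=seed, init_scale=scale,
    )
    return init_vae(cfg)


class TestEncode:
    def test_theta_strictly_positive(self):
        m = toy_model()
        x = np.random.default_rng(0).standard_normal((20, 6)) * 5
        _, theta = encode(m, x)
        assert np.all(theta > 0)

    def test_deterministic(self):
        m = toy_model()
        x = np.random.default_rng(0).standard_normal((4, 6))
        mu1, th1 = encode(m, x)
        mu2, th2 = encode(m, x)
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(th1, th2)

    def test_zero_weights_expose_biases(self):
        """With all weights zero, mu is the mean-map bias and theta the
        positivity transform of the variance-map bias."""
        m = toy_model()
        core = m.core
        for layer in core.enc_hidden + [core.enc_mu, core.enc_s]:
            layer.W[:] = 0.0
        core.enc_mu.b[:] = 1.5
        core.enc_s.b[:] = -0.5
        mu, theta = encode(m, np.zeros((1, 6)))
        np.testing.assert_allclose(mu, 1.5)
        np.testing.assert_allclose(theta, softplus(-0.5) + 1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="input_dim"):
            encode(toy_model(), np.zeros((1, 7)))


class TestReparameterize:
    def test_zero_eps_returns_mu(self):
        mu = np.array([1.0, -2.0])
        z = reparameterize(mu, np.array([4.0, 9.0]), np.zeros(2))
        np.testing.assert_array_equal(z, mu)

    def test_vanishing_theta_collapses_to_mu(self):
        z = reparameterize(np.ones(3), np.full(3, 1e-12), np.ones(3))
        np.testing.assert_allclose(z, 1.0, atol=1e-5)

    def test_sample_moments_match_parameters(self):
        """1e5 reparameterized draws reproduce (mu, theta) within 3 SE."""
        rng = np.random.default_rng(8)
        mu, theta = np.array([0.7]), np.array([2.3])
        n = 100_000
        z = np.array([
            reparameterize(mu, theta, e)[0] for e in rng.standard_normal((n, 1))
        ])
        se_mean = np.sqrt(theta[0] / n)
        assert abs(z.mean() - mu[0]) < 3 * se_mean
        se_var = theta[0] * np.sqrt(2.0 / (n - 1))
        assert abs(z.var(ddof=1) - theta[0]) < 3 * se_var

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            reparameterize(np.zeros(2), np.array([1.0, 0.0]), np.zeros(2))


class TestElbo:
    def test_kl_zero_when_posterior_is_prior(self):
        assert gaussian_kl(np.zeros(5), np.ones(5)) == pytest.approx(0.0)

    def test_kl_closed_form_value(self):
        """1-D KL at mu=1, theta=1 is 0.5 = 0.5*(mu^2 + theta - 1 - ln theta)."""
        assert gaussian_kl(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)

    def test_kl_closed_form_equals_monte_carlo(self):
        """Closed-form KL matches E_eps[log q(z) - log p(z)] by sampling."""
        rng = np.random.default_rng(2)
        mu = np.array([0.3, -1.2, 0.8])
        theta = np.array([0.5, 2.0, 1.3])
        n = 200_000
        eps = rng.standard_normal((n, 3))
        z = mu + np.sqrt(theta) * eps
        log_q = stats.norm.logpdf(z, loc=mu, scale=np.sqrt(theta)).sum(axis=1)
        log_p = stats.norm.logpdf(z).sum(axis=1)
        mc = (log_q - log_p).mean()
        se = (log_q - log_p).std(ddof=1) / np.sqrt(n)
        assert abs(gaussian_kl(mu, theta) - mc) < 3 * se

    def test_report_identity(self):
        m = toy_model()
        x = np.random.default_rng(3).standard_normal((4, 6))
        eps = np.random.default_rng(4).standard_normal((4, 2))
        rep = elbo(m, x, eps)
        assert isinstance(rep, ElboReport)
        assert rep.elbo == pytest.approx(rep.reconstruction - rep.kl)
        assert rep.kl >= 0

    def test_elbo_lower_bounds_linear_gaussian_evidence(self):
        """On a linear-Gaussian decoder the exact log evidence is available:
        p(x) = N(b, W W^T + diag(sigma^2)); the average single-sample ELBO
        must not exceed it (within Monte-Carlo error)."""
        rng = np.random.default_rng(6)
        d, k = 4, 2
        dec_mu = Dense(k, d, rng=rng, scale=0.8, dtype="float64")
        core = GaussianVae(
            enc_hidden=[],
            enc_mu=Dense(d, k, rng=rng, scale=0.5, dtype="float64"),
            enc_s=Dense(d, k, rng=rng, scale=0.5, dtype="float64"),
            dec_hidden=[],
            dec_mu=dec_mu,
            dec_logvar=np.full(d, -0.5),
        )
        cov = dec_mu.W @ dec_mu.W.T + np.diag(np.exp(core.dec_logvar))
        evidence = stats.multivariate_normal(mean=dec_mu.b, cov=cov)
        for _ in range(3):
            x = evidence.rvs(random_state=rng)[None]
            n_mc = 3000
            vals = np.array([
                elbo(core, x, eps[None]).elbo
                for eps in rng.standard_normal((n_mc, k))
            ])
            mc_mean = vals.mean()
            mc_se = vals.std(ddof=1) / np.sqrt(n_mc)
            assert mc_mean <= evidence.logpdf(x[0]) + 3 * mc_se

    def test_gradients_match_finite_differences(self):
        """Analytic ELBO gradients on a 6-4-2-4-6 model, rel err < 1e-4."""
        m = toy_model()
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 6))
        eps = rng.standard_normal((5, 2))
        _, grads = elbo_and_grads(m.core, x, eps)
        for name, p in m.core.params():
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = p[i]
                p[i] = old + 1e-6
                lp = elbo(m.core, x, eps).elbo
                p[i] = old - 1e-6
                lm = elbo(m.core, x, eps).elbo
                p[i] = old
                num[i] = (lp - lm) / 2e-6
            rel = np.abs(num - grads[name]).max() / (np.abs(num).max() + 1e-12)
            assert rel < 1e-4, name


class TestPretrain:
    def test_zero_epochs_is_identity(self, separable_features):
        x, _ = separable_features
        cfg = fast_vae_config(input_dim=40, pretrain_epochs=0)
        m = init_vae(cfg)
        before = {n: p.copy() for n, p in m.core.params()}
        pretrain_layerwise(m, x)
        for name, p in m.core.params():
            np.testing.assert_array_equal(p, before[name], err_msg=name)

    def test_deterministic_replay(self, separable_features):
        x, _ = separable_features
        cfg = fast_vae_config(input_dim=40, pretrain_epochs=2)
        runs = []
        for _ in range(2):
            m = init_vae(cfg)
            pretrain_layerwise(m, x)
            runs.append({n: p.copy() for n, p in m.core.params()})
        for name in runs[0]:
            np.testing.assert_array_equal(runs[0][name], runs[1][name], err_msg=name)

    def test_stage_training_improves_elbo(self, separable_features):
        x, _ = separable_features
        rng = np.random.default_rng(1)
        core = GaussianVae(
            enc_hidden=[],
            enc_mu=Dense(40, 8, rng=rng, scale=0.01, dtype="float32"),
            enc_s=Dense(40, 8, rng=rng, scale=0.01, dtype="float32"),
            dec_hidden=[],
            dec_mu=Dense(8, 40, rng=rng, scale=0.01, dtype="float32"),
            dec_logvar=np.zeros(40, dtype=np.float32),
        )
        hist = train_stage(core, x, epochs=15, batch_size=10, lr=0.05,
                           rng=np.random.default_rng(2))
        assert hist[-1] > hist[0]

    def test_wiring_preserved(self, separable_features):
        x, _ = separable_features
        cfg = fast_vae_config(input_dim=40, pretrain_epochs=2)
        m = init_vae(cfg)
        pretrain_layerwise(m, x)
        assert m.core.input_dim == 40
        assert m.core.dec_mu.n_out == 40
        _, theta = encode(m, x)
        assert np.all(theta > 0)

    def test_empty_features_rejected(self):
        m = init_vae(fast_vae_config(input_dim=40))
        with pytest.raises(ValueError, match="empty"):
            pretrain_layerwise(m, np.zeros((0, 40)))


class TestFinetuneAndPredict:
    def test_zero_learning_rate_is_identity(self, separable_features):
        x, y = separable_features
        cfg = fast_vae_config(input_dim=40, learning_rate=0.0, finetune_epochs=3)
        m = init_vae(cfg)
        before = {n: p.copy() for n, p in m.core.params()}
        finetune(m, x, y)
        for name, p in m.core.params():
            np.testing.assert_array_equal(p, before[name], err_msg=name)

    def test_separable_features_learned(self, separable_features):
        """Pretrain + fine-tune reaches >0.9 training accuracy and >0.8
        held-out kappa on cleanly separated clusters."""
        x, y = separable_features
        m = init_vae(fast_vae_config(input_dim=40))
        pretrain_layerwise(m, x[:40])
        _, hist = finetune(m, x[:40], y[:40])
        assert hist.accuracy[-1] > 0.9
        labels, _ = vae_predict(m, x[40:])
        acc = np.mean(labels == y[40:])
        assert (acc - 0.5) / 0.5 > 0.8  # held-out kappa

    def test_probabilities_and_duplicates(self, separable_features):
        x, y = separable_features
        m = init_vae(fast_vae_config(input_dim=40, finetune_epochs=2))
        finetune(m, x, y)
        dup = np.vstack([x[:3], x[:3]])
        labels, probs = vae_predict(m, dup)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)
        np.testing.assert_array_equal(labels[:3], labels[3:])
        np.testing.assert_array_equal(probs[:3], probs[3:])

    def test_single_class_rejected(self, separable_features):
        x, y = separable_features
        m = init_vae(fast_vae_config(input_dim=40))
        with pytest.raises(ValueError, match="both classes"):
            finetune(m, x[y == 0], y[y == 0])

    def test_dimension_mismatch_rejected(self, separable_features):
        x, y = separable_features
        m = init_vae(fast_vae_config(input_dim=40, finetune_epochs=1))
        finetune(m, x, y)
        with pytest.raises(ValueError, match="input_dim"):
            vae_predict(m, np.zeros((2, 39)))
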