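import numpy as np
import pytest
from scipy.stats import norm

from tipclust.niw_likelihood import (
    NIWParams,
    default_hyperparams,
    log_predictive,
    log_predictive_batch,
    loo_log_predictive,
    niw_posterior,
)


@pytest.fixture
def prior_2d():
    return NIWParams(mu0=np.zeros(2), lambda0=1.0, Psi0=np.eye(2), nu0=4.0)


@pytest.fixture
def prior_1d():
    return NIWParams(mu0=np.array([0.0]), lambda0=1.0, Psi0=np.array([[2.0]]), nu0=3.0)


class TestDefaultHyperparams:
    def test_grand_mean_and_scalars(self, rng):
        X = rng.normal(size=(20, 3))
        pr = default_hyperparams(X)
        assert pr.mu0 == pytest.approx(X.mean(axis=0))
        assert pr.lambda0 == 1.0
        assert pr.nu0 == 3.0

    def test_scatter_convention(self, rng):
        X = rng.normal(size=(15, 2))
        pr = default_hyperparams(X)
        Xc = X - X.mean(axis=0)
        assert pr.Psi0 == pytest.approx((2 - 1) * (Xc.T @ Xc) / 14)

    def test_printed_convention(self, rng):
        X = rng.normal(size=(15, 2))
        pr = default_hyperparams(X, psi0="printed")
        Xc = X - X.mean(axis=0)
        assert pr.Psi0 == pytest.approx(np.linalg.inv(Xc.T @ Xc))

    def test_p1_requires_explicit_psi0(self):
        X = np.array([[-1.0], [1.0]])
        with pytest.raises(ValueError, match="p = 1"):
            default_hyperparams(X)
        pr = default_hyperparams(X, Psi0=np.array([[1.5]]))
        assert pr.Psi0[0, 0] == 1.5

    def test_singular_scatter_rejected(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # rank-1
        with pytest.raises(ValueError, match="singular|positive-definite"):
            default_hyperparams(X, psi0="printed")


class TestNIWPosterior:
    def test_empty_cluster_returns_prior(self, prior_2d):
        post = niw_posterior(prior_2d, np.empty((0, 2)))
        assert post.mu1 == pytest.approx(prior_2d.mu0)
        assert post.lambda1 == prior_2d.lambda0
        assert post.nu1 == prior_2d.nu0
        assert post.Psi1 == pytest.approx(prior_2d.Psi0)

    def test_single_observation_closed_form(self, prior_2d):
        x = np.array([2.0, -1.0])
        post = niw_posterior(prior_2d, x[None, :])
        assert post.mu1 == pytest.approx((prior_2d.mu0 + x) / 2)
        assert post.lambda1 == 2.0
        assert post.nu1 == prior_2d.nu0 + 1

    def test_two_observations_scalar_oracle(self, prior_1d):
        xs = np.array([[1.0], [3.0]])
        post = niw_posterior(prior_1d, xs)
        xbar = 2.0
        S = (1 - 2) ** 2 + (3 - 2) ** 2
        extra = (1 * 2 / (1 + 2)) * (xbar - 0.0) ** 2
        assert post.Psi1[0, 0] == pytest.approx(2.0 + S + extra)
        assert post.mu1[0] == pytest.approx((1 * 0 + 2 * xbar) / 3)

    def test_batch_equals_sequential(self, prior_2d, rng):
        X = rng.normal(size=(7, 2))
        batch = niw_posterior(prior_2d, X)
        seq = prior_2d
        running = []
        for x in X:
            running.append(x)
            seq_post = niw_posterior(prior_2d, np.array(running))
        assert seq_post.mu1 == pytest.approx(batch.mu1, abs=1e-10)
        assert seq_post.Psi1 == pytest.approx(batch.Psi1, abs=1e-10)

    def test_order_invariance(self, prior_2d, rng):
        X = rng.normal(size=(6, 2))
        a = niw_posterior(prior_2d, X)
        b = niw_posterior(prior_2d, X[::-1])
        assert a.mu1 == pytest.approx(b.mu1)
        assert a.Psi1 == pytest.approx(b.Psi1)

    def test_psi1_stays_spd(self, prior_2d, rng):
        for _ in range(20):
            X = rng.normal(size=(int(rng.integers(1, 9)), 2)) * 5
            post = niw_posterior(prior_2d, X)
            assert np.all(np.linalg.eigvalsh(post.Psi1) > 0)


class TestLogPredictive:
    def test_density_integrates_to_one_1d(self, prior_1d):
        post = niw_posterior(prior_1d, np.array([[0.5], [1.5], [-0.3]]))
        grid = np.linspace(-60, 60, 200_001)
        dens = np.exp(log_predictive_batch(grid[:, None], post))
        integral = np.trapezoid(dens, grid)
        assert integral == pytest.approx(1.0, abs=1e-2)

    def test_elliptical_symmetry(self, prior_2d, rng):
        post = niw_posterior(prior_2d, rng.normal(size=(5, 2)))
        v = np.array([0.7, -1.3])
        assert log_predictive(post.mu1 + v, post) == pytest.approx(
            log_predictive(post.mu1 - v, post)
        )

    def test_gaussian_limit_large_nu(self):
        prior = NIWParams(
            mu0=np.array([0.0]), lambda0=1.0, Psi0=np.array([[1.0]]), nu0=3.0
        )
        X = np.random.default_rng(1).normal(2.0, 1.0, size=(5000, 1))
        post = niw_posterior(prior, X)
        nu = post.nu1 - 1 + 1
        var = post.Psi1[0, 0] * (post.lambda1 + 1) / (post.lambda1 * nu) * nu / (nu - 2)
        for x in (1.0, 2.0, 3.5):
            got = log_predictive(np.array([x]), post)
            ref = norm.logpdf(x, post.mu1[0], np.sqrt(var))
            assert got == pytest.approx(ref, abs=1e-3)

    def test_loo_matches_explicit_refits(self, prior_2d, rng):
        Xm = rng.normal(size=(6, 2))
        loo = loo_log_predictive(Xm, prior_2d)
        for i in range(6):
            rest = np.delete(Xm, i, axis=0)
            post = niw_posterior(prior_2d, rest)
            assert loo[i] == pytest.approx(log_predictive(Xm[i], post), abs=1e-10)

    def test_loo_singleton_uses_prior_predictive(self, prior_2d):
        x = np.array([[1.0, 2.0]])
        loo = loo_log_predictive(x, prior_2d)
        empty = niw_posterior(prior_2d, np.empty((0, 2)))
        assert loo[0] == pytest.approx(log_predictive(x[0], empty))


class TestParamValidation:
    def test_bad_lambda0(self):
        with pytest.raises(ValueError):
            NIWParams(np.zeros(2), 0.0, np.eye(2), 4.0)

    def test_bad_nu0(self):
        with pytest.raises(ValueError):
            NIWParams(np.zeros(3), 1.0, np.eye(3), 1.5)

    def test_non_spd_psi0(self):
        with pytest.raises(ValueError):
            NIWParams(np.zeros(2), 1.0, -np.eye(2), 4.0)
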