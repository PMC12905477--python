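import math

import numpy as np
import pytest
from scipy import stats

from hemovasc.inference import (
    BoxTransform,
    GaussianLikelihood,
    adaptive_metropolis,
    discrepancy_cov,
    gaussian_kl,
    make_box_posterior,
    matern32,
    nuts_sample,
    posterior_divergence,
    psrf,
    push_forward,
    PosteriorSamples,
    sample_posterior,
)


class TestMatern32:
    def test_zero_distance(self):
        assert matern32(0.3, 0.3, 0.2, 1.7) == pytest.approx(1.7)

    def test_large_distance_decays(self):
        assert matern32(0.0, 100.0, 0.2, 1.0) < 1e-12

    def test_characteristic_distance_value(self):
        # d = l/sqrt(3) -> sigma^2 * 2/e
        ell = 0.4
        val = matern32(0.0, ell / math.sqrt(3.0), ell, 1.0)
        assert val == pytest.approx(2.0 / math.e, rel=1e-12)

    def test_invalid_lengthscale(self):
        with pytest.raises(ValueError):
            matern32(0.0, 1.0, -1.0, 1.0)


class TestLikelihood:
    def _make(self, times, y, hyper, f):
        return GaussianLikelihood(
            times, {0: y}, lambda theta: {0: f(theta)}, {0: hyper}
        )

    def test_single_point_unit_variance(self):
        lik = GaussianLikelihood(
            np.array([0.0]), {0: np.array([2.0])},
            lambda th: {0: np.array([2.0])},
            {0: (1.0, 0.0, 1.0)},
        )
        # sigma2=0, tau=1 -> Sigma = [1]; y = f
        assert lik.log_likelihood(np.zeros(1)) == pytest.approx(
            -0.5 * math.log(2 * math.pi), rel=1e-6
        )

    def test_white_noise_closed_form(self):
        n = 12
        tau = 0.3
        times = np.linspace(0, 1, n)
        y = np.random.default_rng(0).normal(size=n)
        lik = self._make(times, y, (1.0, 0.0, tau), lambda th: y)
        expect = -0.5 * n * math.log(2 * math.pi) - 0.5 * n * math.log(tau)
        assert lik.log_likelihood(np.zeros(1)) == pytest.approx(
            expect, rel=1e-6
        )

    def test_matches_scipy_multivariate_normal(self, rng):
        n = 15
        times = np.sort(rng.uniform(0, 1, n))
        hyper = (0.2, 2.0, 0.1)
        for _ in range(20):
            y = rng.normal(size=n)
            f = rng.normal(size=n)
            lik = self._make(times, y, hyper, lambda th, f=f: f)
            cov = discrepancy_cov(times, *hyper)
            expect = stats.multivariate_normal.logpdf(y, mean=f, cov=cov)
            assert lik.log_likelihood(np.zeros(1)) == pytest.approx(
                expect, rel=1e-9
            )

    def test_time_permutation_invariance(self, rng):
        n = 10
        times = np.sort(rng.uniform(0, 1, n))
        y = rng.normal(size=n)
        f = rng.normal(size=n)
        hyper = (0.3, 1.0, 0.2)
        base = self._make(times, y, hyper, lambda th: f).log_likelihood(
            np.zeros(1)
        )
        perm = rng.permutation(n)
        permuted = self._make(
            times[perm], y[perm], hyper, lambda th: f[perm]
        ).log_likelihood(np.zeros(1))
        assert permuted == pytest.approx(base, rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        n = 8
        times = np.linspace(0, 1, n)
        y = rng.normal(size=n)
        M = rng.normal(size=(n, 2))

        def fwd(theta):
            return {0: (M @ theta, M)}

        lik = GaussianLikelihood(times, {0: y}, fwd, {0: (0.3, 1.0, 0.2)})
        th = rng.normal(size=2)
        ll, g = lik.log_likelihood(th, with_grad=True)
        for i in range(2):
            e = np.zeros(2)
            e[i] = 1e-6
            fd = (
                lik.log_likelihood(th + e) - lik.log_likelihood(th - e)
            ) / 2e-6
            assert g[i] == pytest.approx(fd, rel=1e-5)


class TestBoxTransform:
    def test_round_trip(self, rng):
        tf = BoxTransform([0.0, 10.0], [1.0, 20.0])
        x = np.array([0.25, 17.0])
        assert np.allclose(tf.to_constrained(tf.to_unconstrained(x)), x)

    def test_jacobian_matches_finite_differences(self, rng):
        tf = BoxTransform([0.0], [2.0])
        u = np.array([0.3])
        h = 1e-6
        fd = (
            tf.to_constrained(u + h) - tf.to_constrained(u - h)
        ) / (2 * h)
        assert tf.dx_du(u)[0] == pytest.approx(fd[0], rel=1e-6)


class TestNUTS:
    def test_conjugate_gaussian_posterior(self, rng):
        """Linear forward map + Gaussian noise: NUTS matches the analytic
        Gaussian posterior within Monte-Carlo error."""
        A = np.array([[1.0, 0.4], [0.0, 1.2], [0.7, -0.3]])
        tau = 0.5
        theta_true = np.array([0.3, -0.6])
        y = A @ theta_true + 0.1 * rng.standard_normal(3)
        prec = A.T @ A / tau + np.eye(2)  # N(0, I) prior
        cov = np.linalg.inv(prec)
        mean = cov @ (A.T @ y / tau)

        def lp_grad(th):
            r = y - A @ th
            lp = -0.5 * float(r @ r) / tau - 0.5 * float(th @ th)
            return lp, A.T @ r / tau - th

        dr, _, _ = nuts_sample(lp_grad, np.zeros(2), 400, 2000, seed=1)
        se = np.sqrt(np.diag(cov) / 200)  # generous effective-sample bound
        assert np.all(np.abs(dr.mean(0) - mean) < 5 * se)
        assert np.allclose(np.cov(dr.T), cov, atol=0.15 * np.max(cov))

    def test_prior_only_recovers_uniform(self):
        """With the likelihood switched off the posterior is the box prior;
        marginals must look uniform (KS test)."""
        tf = BoxTransform([2.0, -1.0], [5.0, 1.0])
        lp_grad = make_box_posterior(
            lambda x, with_grad=False: (0.0, np.zeros(2))
            if with_grad
            else 0.0,
            tf,
        )
        dr, _, _ = nuts_sample(lp_grad, np.zeros(2), 400, 1500, seed=3)
        x = np.apply_along_axis(tf.to_constrained, 1, dr)
        thin = x[::10]
        for j, (lo, hi) in enumerate(((2.0, 5.0), (-1.0, 1.0))):
            p = stats.kstest(
                (thin[:, j] - lo) / (hi - lo), "uniform"
            ).pvalue
            assert p > 0.01

    def test_psrf_near_one_for_identical_target(self):
        def lp_grad(u):
            return -0.5 * float(u @ u), -u

        chains = np.array(
            [
                nuts_sample(lp_grad, np.full(2, s - 1.0), 200, 400,
                            seed=s)[0]
                for s in range(3)
            ]
        )
        assert np.all(psrf(chains) < 1.05)


def test_adaptive_metropolis_gaussian(rng):
    cov = np.array([[1.0, 0.6], [0.6, 1.5]])
    prec = np.linalg.inv(cov)

    def lp(u):
        return -0.5 * float(u @ prec @ u)

    dr, _, diag = adaptive_metropolis(lp, np.zeros(2), n_iter=8000, seed=4)
    assert 0.1 < diag["accept_rate"] < 0.7
    assert np.allclose(np.cov(dr.T), cov, atol=0.3)


class TestKL:
    def test_self_divergence_near_zero(self, rng):
        X = rng.standard_normal((2000, 3))
        Y = rng.standard_normal((2000, 3))
        kl, _ = posterior_divergence(X, Y)
        assert abs(kl) < 0.02

    def test_gaussian_closed_form(self, rng):
        mu_a = np.zeros(2)
        cov_a = np.eye(2)
        mu_b = np.array([0.5, -0.2])
        cov_b = np.array([[1.5, 0.3], [0.3, 0.8]])
        A = rng.multivariate_normal(mu_a, cov_a, 5000)
        B = rng.multivariate_normal(mu_b, cov_b, 5000)
        truth = gaussian_kl(mu_a, cov_a, mu_b, cov_b)
        for est in ("gaussian", "knn"):
            kl, sym = posterior_divergence(A, B, estimator=est)
            assert kl == pytest.approx(truth, rel=0.10)
            assert sym >= kl - 0.02

    def test_nonnegative_up_to_noise(self, rng):
        for _ in range(5):
            A = rng.standard_normal((1000, 2)) + rng.normal(size=2)
            B = rng.standard_normal((1000, 2)) + rng.normal(size=2)
            kl, _ = posterior_divergence(A, B)
            assert kl > -0.02

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            posterior_divergence(np.zeros((50, 2)), np.zeros((200, 2)))


class TestPushForward:
    def test_zero_variance_posterior_collapses(self):
        theta = np.array([1.0, 2.0])
        samples = PosteriorSamples(
            chains=np.tile(theta, (1, 300, 1)), names=("a", "b")
        )

        def forward(th):
            return {1: th[0] * np.ones(5) + th[1]}

        bands = push_forward(samples, forward, n_sub=50, seed=0)
        assert np.allclose(bands[1]["lo"], bands[1]["hi"])
        assert np.allclose(bands[1]["mean"], 3.0)

    def test_prediction_bands_wider_than_credible(self, rng):
        chains = rng.normal(0, 0.1, (2, 200, 1)) + 1.0
        samples = PosteriorSamples(chains=chains, names=("a",))
        times = np.linspace(0, 1, 8)

        def forward(th):
            return {1: th[0] * np.ones(8)}

        bands = push_forward(
            samples, forward, n_sub=100, seed=1,
            noise_hyper={1: (0.2, 0.5, 0.05)}, times=times,
        )
        assert np.all(bands[1]["pred_hi"] >= bands[1]["hi"] - 1e-9)
        assert np.all(bands[1]["pred_lo"] <= bands[1]["lo"] + 1e-9)


class TestJointHyperparameterPosterior:
    def _make(self, rng):
        from hemovasc.inference import JointPosterior

        times = np.linspace(0, 1, 12)
        M = rng.normal(size=(12, 2))
        theta_true = np.array([0.4, 0.7])
        y = {3: M @ theta_true + 0.3 * rng.standard_normal(12)}

        def fwd(theta):
            return {3: (M @ theta, M)}

        return JointPosterior(
            times, y, fwd, lower=[0.0, 0.0], upper=[1.0, 1.0], period_T=1.0
        )

    def test_layout_and_constrain(self, rng):
        jp = self._make(rng)
        assert jp.dim == 2 + 3
        u = jp.init_point(np.random.default_rng(0))
        theta, hyper = jp.constrain(u)
        assert np.all((theta >= 0) & (theta <= 1))
        ell, s2, tau = hyper[3]
        assert 0 < ell < 1.0 and s2 > 0 and tau > 0

    def test_gradient_matches_finite_differences(self, rng):
        jp = self._make(rng)
        u = jp.init_point(np.random.default_rng(1))
        lp, g = jp.logp_and_grad(u)
        for i in range(jp.dim):
            e = np.zeros(jp.dim)
            e[i] = 1e-6
            fd = (jp.logp(u + e) - jp.logp(u - e)) / 2e-6
            assert g[i] == pytest.approx(fd, rel=2e-4, abs=1e-6)

    def test_short_nuts_run_stays_in_support(self, rng):
        jp = self._make(rng)
        dr, lg, _ = nuts_sample(
            jp.logp_and_grad, jp.init_point(np.random.default_rng(2)),
            n_warmup=150, n_draws=200, seed=5,
        )
        assert np.all(np.isfinite(lg))
        theta, hyper = jp.constrain(dr[-1])
        assert np.all((theta > 0) & (theta < 1))
        assert all(v > 0 for v in hyper[3])


def test_sample_posterior_flags_convergence(rng):
    """A well-behaved 1D problem converges within one round."""
    times = np.linspace(0, 1, 10)
    y = 2.0 * np.ones(10)

    def fwd(theta):
        return {0: (theta[0] * np.ones(10), np.ones((10, 1)))}

    lik = GaussianLikelihood(times, {0: y}, fwd, {0: (0.2, 0.1, 0.05)})
    tf = BoxTransform([0.0], [5.0])
    post = sample_posterior(
        lik, tf, [np.array([0.0]), np.array([1.0])], ("a",),
        n_warmup=150, n_draws=250, seed=0,
    )
    assert post.converged
    assert np.all(np.asarray(post.diagnostics["psrf"]) < 1.1)
    lo, hi = post.credible_interval()
    assert lo[0] < 2.0 < hi[0]
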