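"""Bayesian inverse UQ of biophysical parameters from noisy flow waveforms.

Observation model per observed vessel i:

    y_i | theta ~ N(f_i(theta), Sigma_i),
    Sigma_i = K_disc,i + tau_i I,
    K_disc(t, t') = sigma_i^2 (1 + sqrt(3)|t-t'|/l_i) exp(-sqrt(3)|t-t'|/l_i),

a Kennedy-O'Hagan style Gaussian-process model-discrepancy term plus white
observation noise.  Priors: theta uniform over its physiological box,
l_i ~ U(0, T), sigma_i^2 ~ Exp(scale = observed data range), log tau_i ~
N(-2, 1).  Sampling uses the No-U-Turn sampler with dual-averaging step-size
adaptation and a diagonal mass matrix (gradient-based, for emulator forward
maps), or adaptive Metropolis (gradient-free, for solver-in-the-loop ground
truth).  Convergence is monitored by the potential scale reduction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "matern32",
    "discrepancy_cov",
    "GaussianLikelihood",
    "JointPosterior",
    "BoxTransform",
    "nuts_sample",
    "adaptive_metropolis",
    "psrf",
    "sample_posterior",
    "push_forward",
    "gaussian_kl",
    "posterior_divergence",
    "PosteriorSamples",
]


def matern32(t, tp, ell, sigma2):
    """Matern 3/2 covariance sigma^2 (1 + sqrt(3) d/l) exp(-sqrt(3) d/l)."""
    if ell <= 0:
        raise ValueError("lengthscale must be positive")
    d = np.abs(np.asarray(t, float)[..., None] - np.asarray(tp, float)[None])
    s = math.sqrt(3.0) / ell
    out = sigma2 * (1.0 + s * d) * np.exp(-s * d)
    return out if out.ndim > 0 else float(out)


def discrepancy_cov(times, ell, sigma2, tau, jitter=1e-10):
    """Sigma = K_disc + tau I, jitter-stabilised."""
    K = matern32(times, times, ell, sigma2)
    n = len(times)
    return K + (tau + jitter * max(sigma2 + tau, 1.0)) * np.eye(n)


@dataclass
class GaussianLikelihood:
    """Multivariate-normal likelihood over one or more observed vessels.

    ``y``: {vid: (n_t,)}; ``hyper``: {vid: (ell, sigma2, tau)};
    ``forward``: callable theta -> {vid: f or (f, J)} where J is the
    (n_t, dim) Jacobian (needed only for gradient-based sampling).
    """

    times: np.ndarray
    y: dict[int, np.ndarray]
    forward: object
    hyper: dict[int, tuple[float, float, float]]

    def __post_init__(self):
        self._cho = {}
        for vid, (ell, s2, tau) in self.hyper.items():
            self._cho[vid] = cho_factor(
                discrepancy_cov(self.times, ell, s2, tau), lower=True
            )

    def _logdet_half(self, vid):
        c, _ = self._cho[vid]
        return float(np.sum(np.log(np.diag(c))))

    def log_likelihood(self, theta, with_grad=False):
        """Sum over vessels of the MVN log density (Cholesky-based):
        -n_T/2 log 2 pi - 1/2 log|Sigma| - 1/2 r^T Sigma^-1 r."""
        out = self.forward(theta)
        n_t = self.times.size
        ll = 0.0
        grad = 0.0
        for vid, yv in self.y.items():
            fv = out[vid]
            J = None
            if isinstance(fv, tuple):
                fv, J = fv
            r = yv - fv
            alpha = cho_solve(self._cho[vid], r)
            ll += (
                -0.5 * n_t * math.log(2.0 * math.pi)
                - self._logdet_half(vid)
                - 0.5 * float(r @ alpha)
            )
            if with_grad:
                if J is None:
                    raise ValueError("forward map returned no Jacobian")
                grad = grad + J.T @ alpha
        if with_grad:
            return ll, grad
        return ll


class BoxTransform:
    """Logit map between a box [lo, hi]^d and unconstrained space, with
    log-Jacobian (uniform prior over the box becomes logJ alone)."""

    def __init__(self, lower, upper):
        self.lower = np.asarray(lower, float)
        self.upper = np.asarray(upper, float)
        self.width = self.upper - self.lower

    def to_unconstrained(self, x):
        z = np.clip((x - self.lower) / self.width, 1e-12, 1 - 1e-12)
        return np.log(z) - np.log1p(-z)

    def to_constrained(self, u):
        s = 1.0 / (1.0 + np.exp(-u))
        return self.lower + self.width * s

    def log_jac(self, u):
        s = np.clip(1.0 / (1.0 + np.exp(-u)), 1e-300, 1.0 - 1e-16)
        return float(np.sum(np.log(self.width) + np.log(s) + np.log1p(-s)))

    def dx_du(self, u):
        s = 1.0 / (1.0 + np.exp(-u))
        return self.width * s * (1.0 - s)

    def dlogjac_du(self, u):
        s = 1.0 / (1.0 + np.exp(-u))
        return 1.0 - 2.0 * s


def make_box_posterior(loglik, transform: BoxTransform, with_grad=True):
    """Unconstrained log posterior u -> (lp, grad) for a uniform-box prior."""
    if isinstance(loglik, GaussianLikelihood):
        loglik = loglik.log_likelihood

    def lp_grad(u):
        x = transform.to_constrained(u)
        if with_grad:
            ll, g = loglik(x, with_grad=True)
            gu = g * transform.dx_du(u) + transform.dlogjac_du(u)
            return ll + transform.log_jac(u), gu
        return loglik(x) + transform.log_jac(u)

    return lp_grad


class JointPosterior:
    """Joint posterior over theta and the per-vessel discrepancy
    hyperparameters (ell_i, sigma2_i, tau_i).

    Unconstrained layout: [theta (logit over its box)] then, per observed
    vessel, [logit(ell / T), log sigma2, log tau].  Priors: theta uniform,
    ell ~ U(0, T), sigma2 ~ Exponential(scale = observed data range),
    log tau ~ N(-2, 1).  Gradients of the Gaussian log-likelihood with
    respect to the covariance hyperparameters use the standard
    0.5 a' dK a - 0.5 tr(K^-1 dK) identity with a = K^-1 r.
    """

    def __init__(self, times, y, forward, lower, upper, period_T,
                 jitter=1e-8):
        self.times = np.asarray(times, float)
        self.y = {int(k): np.asarray(v, float) for k, v in y.items()}
        self.forward = forward
        self.box = BoxTransform(lower, upper)
        self.T = float(period_T)
        self.jitter = jitter
        self.vids = sorted(self.y)
        self.exp_scale = {
            vid: max(float(np.ptp(self.y[vid])), 1e-12) for vid in self.vids
        }
        self.dim_theta = len(np.atleast_1d(lower))
        self.dim = self.dim_theta + 3 * len(self.vids)
        d = np.abs(self.times[:, None] - self.times[None, :])
        self._d = d

    @property
    def names(self):
        out = [f"theta[{i}]" for i in range(self.dim_theta)]
        for vid in self.vids:
            out += [f"ell[{vid}]", f"sigma2[{vid}]", f"tau[{vid}]"]
        return tuple(out)

    def constrain(self, u):
        u = np.asarray(u, float)
        theta = self.box.to_constrained(u[: self.dim_theta])
        hyper = {}
        for i, vid in enumerate(self.vids):
            ue, us, ut = u[self.dim_theta + 3 * i : self.dim_theta + 3 * i + 3]
            ell = self.T / (1.0 + math.exp(-ue))
            hyper[vid] = (ell, math.exp(us), math.exp(ut))
        return theta, hyper

    def init_point(self, rng):
        u = np.empty(self.dim)
        u[: self.dim_theta] = self.box.to_unconstrained(
            self.box.lower + self.box.width * rng.uniform(0.2, 0.8,
                                                          self.dim_theta)
        )
        for i, vid in enumerate(self.vids):
            o = self.dim_theta + 3 * i
            u[o] = 0.0  # ell = T/2
            u[o + 1] = math.log(0.1 * self.exp_scale[vid] ** 2 + 1e-12)
            u[o + 2] = -2.0 + rng.standard_normal()
        return u

    def logp(self, u):
        return self.logp_and_grad(u, with_grad=False)

    def logp_and_grad(self, u, with_grad=True):
        u = np.asarray(u, float)
        theta, hyper = self.constrain(u)
        out = self.forward(theta)
        n = self.times.size
        d = self._d
        s3 = math.sqrt(3.0)
        lp = 0.0
        grad = np.zeros(self.dim)

        # theta prior (uniform box): log-Jacobian of the logit transform
        ut = u[: self.dim_theta]
        lp += self.box.log_jac(ut)
        if with_grad:
            grad[: self.dim_theta] += self.box.dlogjac_du(ut)

        for i, vid in enumerate(self.vids):
            o = self.dim_theta + 3 * i
            ue, us_, ut_ = u[o], u[o + 1], u[o + 2]
            ell, sig2, tau = hyper[vid]
            se = 1.0 / (1.0 + math.exp(-ue))
            # priors: ell ~ U(0,T) via logit (Jacobian), sigma2 ~ Exp,
            # log tau ~ N(-2, 1)
            lp += math.log(self.T * se * (1 - se) + 1e-300)
            lp += -sig2 / self.exp_scale[vid] + us_
            lp += -0.5 * (ut_ + 2.0) ** 2
            if with_grad:
                grad[o] += 1.0 - 2.0 * se
                grad[o + 1] += -sig2 / self.exp_scale[vid] + 1.0
                grad[o + 2] += -(ut_ + 2.0)

            sdl = s3 * d / ell
            E = np.exp(-sdl)
            M = (1.0 + sdl) * E
            K = sig2 * M + (tau + self.jitter * (sig2 + tau)) * np.eye(n)
            fv = out[vid]
            J = None
            if isinstance(fv, tuple):
                fv, J = fv
            r = self.y[vid] - fv
            try:
                cho = cho_factor(K, lower=True)
            except np.linalg.LinAlgError:
                return (-np.inf, grad * 0) if with_grad else -np.inf
            alpha = cho_solve(cho, r)
            lp += (
                -0.5 * n * math.log(2 * math.pi)
                - float(np.sum(np.log(np.diag(cho[0]))))
                - 0.5 * float(r @ alpha)
            )
            if with_grad:
                if J is None:
                    raise ValueError("forward map returned no Jacobian")
                grad[: self.dim_theta] += (
                    J.T @ alpha
                ) * self.box.dx_du(ut)
                Kinv = cho_solve(cho, np.eye(n))

                def dlp(dK):
                    return 0.5 * float(alpha @ dK @ alpha) - 0.5 * float(
                        np.trace(Kinv @ dK)
                    )

                dK_dell = sig2 * (3.0 * d**2 / ell**3) * E
                dK_dsig = M + self.jitter * np.eye(n)
                dK_dtau = (1.0 + self.jitter) * np.eye(n)
                grad[o] += dlp(dK_dell) * self.T * se * (1 - se)
                grad[o + 1] += dlp(dK_dsig) * sig2
                grad[o + 2] += dlp(dK_dtau) * tau
        return (lp, grad) if with_grad else lp


# ---------------------------------------------------------------------------
# NUTS (No-U-Turn sampler, efficient variant with dual averaging)
# ---------------------------------------------------------------------------


def _leapfrog(lp_grad, q, p, grad, eps, inv_mass):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * inv_mass * p1
    lp1, grad1 = lp_grad(q1)
    p2 = p1 + 0.5 * eps * grad1
    return q1, p2, lp1, grad1


def _find_reasonable_eps(lp_grad, q, rng, inv_mass):
    eps = 1.0
    lp, grad = lp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    q1, p1, lp1, _ = _leapfrog(lp_grad, q, p, grad, eps, inv_mass)
    h0 = lp - 0.5 * float(p * inv_mass @ p)
    h1 = lp1 - 0.5 * float(p1 * inv_mass @ p1)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if h1 - h0 > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**a
        q1, p1, lp1, _ = _leapfrog(lp_grad, q, p, grad, eps, inv_mass)
        h1 = lp1 - 0.5 * float(p1 * inv_mass @ p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= a * math.log(0.5):
            break
    return eps


def nuts_sample(
    lp_grad,
    u0,
    n_warmup=300,
    n_draws=500,
    seed=0,
    target_accept=0.8,
    max_depth=8,
):
    """One NUTS chain; returns (draws, logps, diagnostics).

    ``lp_grad(u) -> (logp, grad)``.  Step size is tuned by dual averaging
    over the warmup; a diagonal mass matrix is estimated from the second
    half of warmup draws.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(u0, float).copy()
    d = q.size
    inv_mass = np.ones(d)
    eps = _find_reasonable_eps(lp_grad, q, rng, inv_mass)
    mu = math.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    lp, grad = lp_grad(q)
    draws = np.empty((n_draws, d))
    logps = np.empty(n_draws)
    warm_draws = []
    n_total = n_warmup + n_draws
    half = n_warmup // 2
    divergences = 0

    def build_tree(q, p, grad, lp, logu, v, j, eps, h0):
        nonlocal divergences
        if j == 0:
            q1, p1, lp1, grad1 = _leapfrog(lp_grad, q, p, grad, v * eps,
                                           inv_mass)
            h1 = lp1 - 0.5 * float(p1 * inv_mass @ p1)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = 1 if logu <= h1 else 0
            s1 = 1 if logu < h1 + 1000.0 else 0
            if h1 - h0 < -1000.0:
                divergences += 1
            alpha = min(1.0, math.exp(min(h1 - h0, 0.0)))
            return q1, p1, grad1, lp1, q1, p1, grad1, lp1, q1, lp1, grad1, \
                n1, s1, alpha, 1
        (qm, pm, gm, lm, qp, pp, gp, lpp, qs, ls, gs, n1, s1, a1, na1) = (
            build_tree(q, p, grad, lp, logu, v, j - 1, eps, h0)
        )
        if s1:
            if v == -1:
                (qm, pm, gm, lm, _, _, _, _, qs2, ls2, gs2, n2, s2, a2, na2) = (
                    build_tree(qm, pm, gm, lm, logu, v, j - 1, eps, h0)
                )
            else:
                (_, _, _, _, qp, pp, gp, lpp, qs2, ls2, gs2, n2, s2, a2,
                 na2) = build_tree(qp, pp, gp, lpp, logu, v, j - 1, eps, h0)
            if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
                qs, ls, gs = qs2, ls2, gs2
            dq = qp - qm
            s1 = (
                s2
                * (1 if float(dq * inv_mass @ pm) >= 0 else 0)
                * (1 if float(dq * inv_mass @ pp) >= 0 else 0)
            )
            n1 += n2
            a1 += a2
            na1 += na2
        return qm, pm, gm, lm, qp, pp, gp, lpp, qs, ls, gs, n1, s1, a1, na1

    for it in range(n_total):
        p0 = rng.standard_normal(d) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * float(p0 * inv_mass @ p0)
        logu = h0 + math.log(rng.random() + 1e-300)
        qm = qp = q
        pm = pp = p0
        gm = gp = grad
        lm = lpp = lp
        q_new, lp_new, grad_new = q, lp, grad
        j, n, s = 0, 1, 1
        alpha_sum, n_alpha = 0.0, 1
        while s and j < max_depth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                (qm, pm, gm, lm, _, _, _, _, qs, ls, gs, n1, s1, a1, na1) = (
                    build_tree(qm, pm, gm, lm, logu, v, j, eps, h0)
                )
            else:
                (_, _, _, _, qp, pp, gp, lpp, qs, ls, gs, n1, s1, a1, na1) = (
                    build_tree(qp, pp, gp, lpp, logu, v, j, eps, h0)
                )
            if s1 and rng.random() < min(1.0, n1 / n):
                q_new, lp_new, grad_new = qs, ls, gs
            n += n1
            dq = qp - qm
            s = (
                s1
                * (1 if float(dq * inv_mass @ pm) >= 0 else 0)
                * (1 if float(dq * inv_mass @ pp) >= 0 else 0)
            )
            alpha_sum, n_alpha = alpha_sum + a1, n_alpha + na1
            j += 1
        q, lp, grad = q_new, lp_new, grad_new

        if it < n_warmup:
            # dual averaging on the acceptance statistic
            w = 1.0 / (it + 1 + t0)
            h_bar = (1 - w) * h_bar + w * (
                target_accept - alpha_sum / max(n_alpha, 1)
            )
            log_eps = mu - math.sqrt(it + 1) / gamma * h_bar
            pw = (it + 1) ** (-kappa)
            log_eps_bar = pw * log_eps + (1 - pw) * log_eps_bar
            eps = math.exp(log_eps)
            if it >= half:
                warm_draws.append(q.copy())
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
                if len(warm_draws) >= 10:
                    var = np.var(np.array(warm_draws), axis=0)
                    inv_mass = np.maximum(var, 1e-8)
        else:
            draws[it - n_warmup] = q
            logps[it - n_warmup] = lp
    return draws, logps, {"step_size": eps, "divergences": divergences}


# ---------------------------------------------------------------------------
# adaptive Metropolis (gradient-free; solver-in-the-loop ground truth)
# ---------------------------------------------------------------------------


def adaptive_metropolis(
    lp, u0, n_iter=4000, n_warmup=None, seed=0, scale0=0.1
):
    """Haario-style adaptive random-walk Metropolis in unconstrained space."""
    rng = np.random.default_rng(seed)
    u = np.asarray(u0, float).copy()
    d = u.size
    n_warmup = n_iter // 2 if n_warmup is None else n_warmup
    cov = (scale0**2) * np.eye(d)
    chol = np.linalg.cholesky(cov)
    cur = lp(u)
    draws = np.empty((n_iter, d))
    logps = np.empty(n_iter)
    acc = 0
    sd = 2.38**2 / d
    mean = u.copy()
    M2 = np.zeros((d, d))
    for it in range(n_iter):
        prop = u + chol @ rng.standard_normal(d)
        new = lp(prop)
        if math.log(rng.random() + 1e-300) < new - cur:
            u, cur = prop, new
            acc += 1
        draws[it] = u
        logps[it] = cur
        delta = u - mean
        mean += delta / (it + 1)
        M2 += np.outer(delta, u - mean)
        if 50 <= it < n_warmup and it % 25 == 0:
            emp = M2 / it
            cov = sd * emp + sd * 1e-8 * np.eye(d)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass
    return draws[n_warmup:], logps[n_warmup:], {"accept_rate": acc / n_iter}


# ---------------------------------------------------------------------------
# diagnostics and posterior summaries
# ---------------------------------------------------------------------------


def psrf(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per parameter; chains has shape
    (n_chains, n_draws, dim)."""
    import arviz as az

    return np.asarray(
        az.rhat(az.convert_to_dataset(chains)).to_array()
    ).ravel()


@dataclass
class PosteriorSamples:
    """Draws in constrained space, (n_chains, n_draws, dim), plus names."""

    chains: np.ndarray
    names: tuple[str, ...]
    logps: np.ndarray | None = None
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    def credible_interval(self, level=0.95):
        a = 100 * (1 - level) / 2
        return np.percentile(self.flat, [a, 100 - a], axis=0)


def sample_posterior(
    loglik,
    transform: BoxTransform,
    u0s,
    names,
    method="nuts",
    n_warmup=300,
    n_draws=500,
    seed=0,
    psrf_target=1.1,
    max_rounds=3,
    extra_draws=0,
) -> PosteriorSamples:
    """Run several chains, monitor PSRF, extend until converged (or budget).

    ``loglik(theta, with_grad=...)`` as in :class:`GaussianLikelihood`;
    chains start from ``u0s`` (list of unconstrained points).
    """
    lp_grad = make_box_posterior(loglik, transform, with_grad=(method == "nuts"))
    all_chains = None
    all_logps = None
    converged = False
    for rnd in range(max_rounds):
        chains = []
        logps = []
        for ci, u0 in enumerate(u0s):
            cs = seed + 7919 * ci + 104729 * rnd
            if method == "nuts":
                dr, lg, _ = nuts_sample(
                    lp_grad, u0, n_warmup=n_warmup, n_draws=n_draws, seed=cs
                )
            else:
                dr, lg, _ = adaptive_metropolis(
                    lp_grad, u0, n_iter=n_warmup + n_draws,
                    n_warmup=n_warmup, seed=cs,
                )
            chains.append(dr)
            logps.append(lg)
        chains = np.array(chains)
        logps = np.array(logps)
        if all_chains is None:
            all_chains = chains
            all_logps = logps
        else:
            all_chains = np.concatenate([all_chains, chains], axis=1)
            all_logps = np.concatenate([all_logps, logps], axis=1)
        r = psrf(all_chains)
        if np.all(r < psrf_target):
            converged = True
            break
        u0s = [c[-1] for c in all_chains]
    if converged and extra_draws:
        more = []
        for ci, u0 in enumerate(all_chains[:, -1]):
            cs = seed + 13 * ci + 999331
            if method == "nuts":
                dr, _, _ = nuts_sample(
                    lp_grad, u0, n_warmup=max(50, n_warmup // 4),
                    n_draws=extra_draws, seed=cs,
                )
            else:
                dr, _, _ = adaptive_metropolis(
                    lp_grad, u0, n_iter=extra_draws + 100, n_warmup=100,
                    seed=cs,
                )
            more.append(dr)
        all_chains = np.concatenate([all_chains, np.array(more)], axis=1)
        all_logps = None
    const = np.apply_along_axis(
        transform.to_constrained, -1, all_chains
    )
    return PosteriorSamples(
        chains=const,
        names=tuple(names),
        logps=all_logps,
        converged=converged,
        diagnostics={"psrf": psrf(all_chains).tolist()},
    )


def push_forward(
    samples: PosteriorSamples,
    forward,
    n_sub=50,
    seed=0,
    noise_hyper=None,
    times=None,
    level=0.95,
    n_noise=20,
):
    """Propagate posterior draws through a forward map.

    Returns {vid: dict(mean, lo, hi, pred_lo, pred_hi, draws)} with
    pointwise credible bands and (when noise hyperparameters are given)
    prediction bands that add observation noise.
    """
    rng = np.random.default_rng(seed)
    flat = samples.flat
    idx = (
        np.arange(len(flat))
        if n_sub >= len(flat)
        else rng.choice(len(flat), n_sub, replace=False)
    )
    outs = {}
    for i in idx:
        res = forward(flat[i])
        for vid, f in res.items():
            if isinstance(f, tuple):
                f = f[0]
            outs.setdefault(vid, []).append(np.asarray(f))
    a = 100 * (1 - level) / 2
    bands = {}
    for vid, rows in outs.items():
        M = np.array(rows)
        b = {
            "mean": M.mean(0),
            "lo": np.percentile(M, a, axis=0),
            "hi": np.percentile(M, 100 - a, axis=0),
            "draws": M,
        }
        if noise_hyper is not None and times is not None:
            ell, s2, tau = noise_hyper[vid]
            cov = discrepancy_cov(times, ell, s2, tau)
            L = np.linalg.cholesky(cov)
            # several noise replicates per posterior draw stabilise the
            # tail quantiles of the prediction bands
            rep = np.repeat(M, n_noise, axis=0)
            noisy = rep + (
                L @ rng.standard_normal((len(rep), len(times))).T
            ).T
            b["pred_lo"] = np.percentile(noisy, a, axis=0)
            b["pred_hi"] = np.percentile(noisy, 100 - a, axis=0)
        bands[vid] = b
    return bands


def gaussian_kl(mu_a, cov_a, mu_b, cov_b):
    """Closed-form KL(N_a || N_b)."""
    d = len(mu_a)
    cb = cho_factor(cov_b, lower=True)
    diff = np.asarray(mu_b) - np.asarray(mu_a)
    tr = np.trace(cho_solve(cb, cov_a))
    quad = float(diff @ cho_solve(cb, diff))
    _, ld_a = np.linalg.slogdet(cov_a)
    _, ld_b = np.linalg.slogdet(cov_b)
    return 0.5 * (tr + quad - d + ld_b - ld_a)


def posterior_divergence(samples_a, samples_b, estimator="gaussian"):
    """KL(a || b) between two sample sets over the same parameter space.

    Default: moment-matched Gaussian KL.  ``estimator='knn'`` uses the
    nearest-neighbour density-ratio estimator instead.  Returns
    (kl_ab, kl_symmetric).
    """
    A = (
        samples_a.flat
        if isinstance(samples_a, PosteriorSamples)
        else np.asarray(samples_a)
    )
    B = (
        samples_b.flat
        if isinstance(samples_b, PosteriorSamples)
        else np.asarray(samples_b)
    )
    if len(A) < 100 or len(B) < 100:
        raise ValueError("need at least 100 samples per set")
    if estimator == "gaussian":
        ka = gaussian_kl(A.mean(0), np.cov(A.T) + 1e-12 * np.eye(A.shape[1]),
                         B.mean(0), np.cov(B.T) + 1e-12 * np.eye(B.shape[1]))
        kb = gaussian_kl(B.mean(0), np.cov(B.T) + 1e-12 * np.eye(B.shape[1]),
                         A.mean(0), np.cov(A.T) + 1e-12 * np.eye(A.shape[1]))
    elif estimator == "knn":
        ka = _knn_kl(A, B)
        kb = _knn_kl(B, A)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return ka, ka + kb


def _knn_kl(A, B):
    """1-nearest-neighbour KL estimator (Wang-Kulkarni-Verdu)."""
    from scipy.spatial import cKDTree

    n, d = A.shape
    m = B.shape[0]
    ta = cKDTree(A)
    tb = cKDTree(B)
    ra = ta.query(A, k=2)[0][:, 1]
    rb = tb.query(A, k=1)[0]
    ra = np.maximum(ra, 1e-300)
    rb = np.maximum(rb, 1e-300)
    return float(d * np.mean(np.log(rb / ra)) + math.log(m / (n - 1)))
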