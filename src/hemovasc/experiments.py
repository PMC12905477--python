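"""Experiment designs, simulation datasets, metrics, and synthetic noisy
observations.

The emulator study draws biophysical parameter vectors from a Latin
hypercube over their physiological box, runs the 1D solver for each, and
keeps flow/pressure at vessel midpoints at a small number of equidistant
times (20 by default, mirroring the amount of waveform data a clinic
typically provides).  Synthetic "measured" flow is a solver run at a known
true parameter vector plus correlated noise drawn from the same Matern 3/2
discrepancy process the likelihood assumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .inference import discrepancy_cov
from .network import BiophysicalParams, ParameterSpace, VascularNetwork
from .solver import SolverConfig, SolverError, build_kernels, sample_midpoint, simulate

__all__ = [
    "lhs_design",
    "SimDataset",
    "build_sim_dataset",
    "metrics",
    "NoisyObservations",
    "generate_noisy_observations",
]

log = logging.getLogger(__name__)


def lhs_design(space: ParameterSpace, n: int, seed: int = 0) -> np.ndarray:
    """Maximin-improved Latin hypercube design scaled into the bounds."""
    if n < 1:
        raise ValueError("need n >= 1")
    sampler = qmc.LatinHypercube(
        d=space.dim, seed=seed,
        optimization="random-cd" if 1 < n <= 64 else None,
    )
    return space.denormalise(sampler.random(n))


@dataclass
class SimDataset:
    """Midpoint flow/pressure of solver runs over a parameter design."""

    thetas: np.ndarray  # (n, dim)
    times: np.ndarray  # (n_t,)
    q: dict[int, np.ndarray]  # vid -> (n, n_t) mL/s
    p: dict[int, np.ndarray]  # vid -> (n, n_t) barye
    space: ParameterSpace
    failed: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.thetas)

    def subset(self, idx) -> "SimDataset":
        idx = np.asarray(idx)
        return SimDataset(
            thetas=self.thetas[idx],
            times=self.times,
            q={v: a[idx] for v, a in self.q.items()},
            p={v: a[idx] for v, a in self.p.items()},
            space=self.space,
        )

    def split(self, n_test: int, seed: int = 0):
        """Disjoint (train, test) datasets."""
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.n)
        return self.subset(perm[n_test:]), self.subset(perm[:n_test])

    def stats(self) -> dict[int, dict[str, float]]:
        return {
            vid: {
                "q_mean": float(self.q[vid].mean()),
                "q_std": float(self.q[vid].std()),
                "p_mean": float(self.p[vid].mean()),
                "p_std": float(self.p[vid].std()),
            }
            for vid in self.q
        }

    def flat_batch(self, vid):
        """(t, Theta, q, p) flattened over (simulation, time) pairs."""
        n, n_t = self.q[vid].shape
        t = np.tile(self.times, n)
        Theta = np.repeat(self.thetas, n_t, axis=0)
        return t, Theta, self.q[vid].ravel(), self.p[vid].ravel()


def build_sim_dataset(
    network: VascularNetwork,
    space: ParameterSpace,
    base_params: BiophysicalParams,
    design: np.ndarray,
    inflow,
    config: SolverConfig | None = None,
    n_t: int = 20,
) -> SimDataset:
    """Run the solver for every design point; failed runs (non-physiological
    parameter draws) are excluded and logged."""
    config = config or SolverConfig()
    times = None
    rows_q: dict[int, list] = {vid: [] for vid in network.vessels}
    rows_p: dict[int, list] = {vid: [] for vid in network.vessels}
    kept = []
    failed = []
    for i, theta in enumerate(np.atleast_2d(design)):
        params = space.update_params(base_params, theta)
        try:
            kernels = build_kernels(
                network, params, config.time_steps_per_period
            )
            res = simulate(network, params, inflow, config, kernels=kernels)
        except (SolverError, FloatingPointError) as exc:
            log.warning("design point %d failed: %s", i, exc)
            failed.append(i)
            continue
        for vid, fld in res.fields.items():
            t, qm, pm = sample_midpoint(fld, n_t)
            rows_q[vid].append(qm)
            rows_p[vid].append(pm)
            times = t
        kept.append(i)
    if not kept:
        raise RuntimeError("every solver run in the design failed")
    if failed:
        log.warning(
            "excluded %d/%d design points (coverage of the design is "
            "reduced accordingly)", len(failed), len(np.atleast_2d(design)),
        )
    return SimDataset(
        thetas=np.atleast_2d(design)[kept],
        times=times,
        q={v: np.array(a) for v, a in rows_q.items()},
        p={v: np.array(a) for v, a in rows_p.items()},
        space=space,
        failed=failed,
    )


def metrics(predicted, truth) -> dict[str, float]:
    """RMSE, MAE, MaxAE and relative L2 (ratio of sums of squares) of one
    predicted series against the reference."""
    predicted = np.asarray(predicted, float)
    truth = np.asarray(truth, float)
    if predicted.shape != truth.shape:
        raise ValueError("series length mismatch")
    d = predicted - truth
    denom = float((truth**2).sum())
    return {
        "rmse": float(np.sqrt((d**2).mean())),
        "mae": float(np.abs(d).mean()),
        "maxae": float(np.abs(d).max()),
        "rel_l2": float((d**2).sum() / denom) if denom > 0 else np.inf,
    }


@dataclass
class NoisyObservations:
    """Synthetic measured flow: solver truth plus correlated GP noise."""

    vessel_ids: tuple[int, ...]
    times: np.ndarray
    y: dict[int, np.ndarray]
    f_true: dict[int, np.ndarray]
    theta_true: np.ndarray
    hyper: dict[int, tuple[float, float, float]]  # (ell, sigma2, tau)
    seed: int


def generate_noisy_observations(
    network: VascularNetwork,
    space: ParameterSpace,
    base_params: BiophysicalParams,
    theta_true,
    vessel_ids,
    inflow,
    config: SolverConfig | None = None,
    n_t: int = 20,
    snr: float = 10.0,
    ell: float | None = None,
    tau_frac: float = 0.1,
    seed: int = 0,
    sim_result=None,
) -> NoisyObservations:
    """y_i = f_i(theta_true) + e_i, e_i ~ N(0, K_disc + tau I).

    sigma_i^2 is set per vessel to hit the target signal-to-noise ratio
    (variance of the waveform / sigma^2 = snr); the Matern lengthscale is
    shared (default T/4) as is tau = tau_frac * sigma_i^2.
    """
    rng = np.random.default_rng(seed)
    params = space.update_params(base_params, np.asarray(theta_true, float))
    if sim_result is None:
        sim_result = simulate(network, params, inflow, config)
    ell = params.period_T / 4.0 if ell is None else ell
    y = {}
    f_true = {}
    hyper = {}
    times = None
    for vid in vessel_ids:
        t, qm, _ = sample_midpoint(sim_result.fields[vid], n_t)
        times = t
        s2 = float(qm.var() / snr)
        tau = tau_frac * s2
        cov = discrepancy_cov(t, ell, s2, tau)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn("observation covariance needed extra jitter")
            L = np.linalg.cholesky(cov + 1e-8 * np.eye(len(t)))
        e = L @ rng.standard_normal(n_t) if s2 > 0 else np.zeros(n_t)
        y[vid] = qm + e
        f_true[vid] = qm
        hyper[vid] = (ell, s2, tau)
    return NoisyObservations(
        vessel_ids=tuple(vessel_ids),
        times=times,
        y=y,
        f_true=f_true,
        theta_true=np.asarray(theta_true, float),
        hyper=hyper,
        seed=seed,
    )
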