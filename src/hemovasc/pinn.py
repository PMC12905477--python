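"""Physics-informed neural emulator of the 1D haemodynamics solver.

One tanh network per vessel maps (x, cos 2*pi*t/T, sin 2*pi*t/T,
theta_normalised) -> (q_hat, p_hat).  Periodicity is exact through the time
embedding; the measured inflow is exact at the network inlet through output
mixing q_tilde = cos(pi x / 2L) q_in(t) + sin(pi x / 2L) q_hat on the root
vessel.  Cross-sectional area follows from predicted pressure through the
wall law, so the PDE residuals involve only network outputs and their
input derivatives.

Training minimises a weighted sum of four losses -- junction continuity,
PDE residuals, structured-tree outflow convolution mismatch, and simulator
data mismatch -- with weights balanced by the gradient-norm moving-average
rule (lambda_i,new = sum_j ||grad L_j|| / ||grad L_i||, exponential moving
average with decay gamma every few steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import BiophysicalParams, ParameterSpace, VascularNetwork
from .nn import MLP, Adam, ArchSpec, cosine_lr
from .impedance import ImpedanceKernel

__all__ = [
    "NetworkEmulator",
    "TrainConfig",
    "CollocationSet",
    "make_collocation",
    "conv_matrix",
]


def conv_matrix(kernel: ImpedanceKernel, n_times: int) -> np.ndarray:
    """Dense matrix C with (C q)_j = periodic convolution of flow samples
    with the impedance kernel at n_times equidistant times."""
    m = n_times
    Zm = _resample_Z(kernel, m)
    C = np.empty((m, m))
    eye = np.eye(m)
    for j in range(m):
        C[:, j] = np.fft.ifft(np.fft.fft(eye[:, j]) * Zm).real
    return C


def _resample_Z(kernel: ImpedanceKernel, m: int) -> np.ndarray:
    """Impedance harmonics for an m-point time grid (m <= kernel.m)."""
    if m == kernel.m:
        return kernel.Z_root
    if m > kernel.m or m % 2:
        raise ValueError("need even m not exceeding the kernel resolution")
    Z = np.empty(m, complex)
    Z[: m // 2 + 1] = kernel.Z_root[: m // 2 + 1]
    Z[m // 2] = Z[m // 2].real
    Z[m // 2 + 1 :] = np.conj(Z[1 : m // 2][::-1])
    return Z


@dataclass
class _VesselCtx:
    vid: int
    L: float
    r0: float
    A0: float
    group: int
    is_root: bool
    q_mean: float = 0.0
    q_std: float = 1.0
    p_mean: float = 0.0
    p_std: float = 1.0


@dataclass
class TrainConfig:
    steps: int = 3000
    batch_pde: int = 256
    batch_bif: int = 256
    batch_data: int = 256
    lr0: float = 1e-3
    lr_min: float = 1e-4
    gamma: float = 0.9  # weight-update moving-average decay
    weight_update_every: int = 5
    mode: str = "pinn"  # pinn | data_only | physics_only
    seed: int = 0
    log_every: int = 50


@dataclass
class CollocationSet:
    """Sampled training inputs for the physics losses.

    pde: per-vessel (x, t, Theta); bif: shared (t, Theta); imp: design Theta
    with per-terminal convolution matrices at m_imp times.
    """

    pde: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    bif_t: np.ndarray
    bif_theta: np.ndarray
    imp_theta: np.ndarray
    imp_conv: dict[int, list[np.ndarray]]  # vid -> [C_i per design point]
    imp_times: np.ndarray


class NetworkEmulator:
    """Per-vessel PINN surrogates over space x time x biophysical inputs."""

    def __init__(
        self,
        network: VascularNetwork,
        space: ParameterSpace,
        base_params: BiophysicalParams,
        inflow_gp,
        width: int = 32,
        depth: int = 3,
        modified: bool = False,
        rwf: bool = False,
        seed: int = 0,
    ):
        self.network = network
        self.space = space
        self.base = base_params
        self.inflow = inflow_gp
        self.T = base_params.period_T
        in_dim = 3 + space.dim
        self.arch = ArchSpec(
            in_dim=in_dim, width=width, depth=depth, modified=modified, rwf=rwf
        )
        self.ctx: dict[int, _VesselCtx] = {}
        self.nets: dict[int, MLP] = {}
        for i, vid in enumerate(network.ordered_ids()):
            v = network.vessels[vid]
            self.ctx[vid] = _VesselCtx(
                vid=vid,
                L=v.length_L,
                r0=v.radius_r0,
                A0=v.A0,
                group=v.group,
                is_root=(vid == network.root.id),
            )
            self.nets[vid] = MLP(self.arch, seed=seed * 1000 + i)
        self.loss_weights = {"bif": 1.0, "pde": 1.0, "imp": 1.0, "sim": 1.0}
        self.history: dict[str, list] = {"loss": [], "weights": []}

    # ------------------------------------------------------------------
    def set_normalisation(self, stats: dict[int, dict[str, float]]):
        """Per-vessel output standardisation from simulation data."""
        for vid, st in stats.items():
            c = self.ctx[vid]
            c.q_mean = float(st["q_mean"])
            c.q_std = float(max(st["q_std"], 1e-9))
            c.p_mean = float(st["p_mean"])
            c.p_std = float(max(st["p_std"], 1e-9))

    # -- embeddings ----------------------------------------------------
    def embed(self, vid, x, t, Theta, clip=False):
        """Network inputs: x/L, the periodic time features, and min-max
        scaled theta.  t and t + kT embed identically by construction."""
        c = self.ctx[vid]
        x = np.asarray(x, float)
        t = np.asarray(t, float)
        Theta = np.atleast_2d(np.asarray(Theta, float))
        Z = self.space.normalise(Theta)
        if clip:
            Z = np.clip(Z, 0.0, 1.0)
        elif np.any(Z < -1e-9) or np.any(Z > 1 + 1e-9):
            raise ValueError("theta outside the declared bounds")
        ang = 2.0 * np.pi * t / self.T
        return np.column_stack(
            [x / c.L, np.cos(ang), np.sin(ang), Z]
        )

    def _xt_tangents(self, vid, t, n):
        """Input directions for d/dx and d/dt of the embedded inputs."""
        c = self.ctx[vid]
        D = 3 + self.space.dim
        S = np.zeros((2, n, D))
        S[0, :, 0] = 1.0 / c.L
        ang = 2.0 * np.pi * np.asarray(t, float) / self.T
        w = 2.0 * np.pi / self.T
        S[1, :, 1] = -w * np.sin(ang)
        S[1, :, 2] = w * np.cos(ang)
        return S

    def _theta_tangents(self, n):
        D = 3 + self.space.dim
        K = self.space.dim
        S = np.zeros((K, n, D))
        for k in range(K):
            S[k, :, 3 + k] = 1.0 / (self.space.upper[k] - self.space.lower[k])
        return S

    # -- wall stiffness per sample -------------------------------------
    def _component(self, Theta, name, default):
        if name in self.space.names:
            return Theta[:, self.space.names.index(name)]
        return np.full(len(Theta), default)

    def _f_wall(self, vid, Theta):
        c = self.ctx[vid]
        g = min(c.group, len(self.base.f3_large_by_group) - 1)
        f2 = self._component(Theta, "f2_large", self.base.f2_large)
        f3 = self._component(
            Theta, f"f3_large[{g}]", self.base.f3_large_by_group[g]
        )
        return self.base.f1_large * np.exp(-f2 * c.r0) + f3

    # -- prediction ----------------------------------------------------
    def predict(self, vid, x, t, Theta, with_area=False, clip=False):
        """Physical flow and pressure (and optionally area) predictions.

        The root vessel mixes the inflow surrogate into the flow output so
        q_tilde(0, t, theta) = q_in(t) identically.
        """
        c = self.ctx[vid]
        x = np.broadcast_to(np.asarray(x, float), np.shape(t) or (1,)).ravel()
        t = np.broadcast_to(np.asarray(t, float), x.shape).ravel()
        Theta = np.atleast_2d(Theta)
        if Theta.shape[0] == 1:
            Theta = np.broadcast_to(Theta, (x.size, Theta.shape[1]))
        X = self.embed(vid, x, t, Theta, clip=clip)
        Y, _, _ = self.nets[vid].forward(X)
        q = c.q_mean + c.q_std * Y[:, 0]
        p = c.p_mean + c.p_std * Y[:, 1]
        if c.is_root:
            mix = 0.5 * np.pi * x / c.L
            q = np.cos(mix) * self.inflow.qin(t) + np.sin(mix) * q
        if not with_area:
            return q, p
        f = self._f_wall(vid, Theta)
        bracket = 3.0 * (p - self.base.p0) / (4.0 * f) + 1.0
        A = np.where(bracket > 0, c.A0 * bracket**2, np.nan)
        return q, p, A

    def predict_midpoint(self, vid, t, Theta):
        c = self.ctx[vid]
        return self.predict(vid, c.L / 2.0, t, Theta)

    def flow_with_theta_grad(self, vid, x, t, Theta1):
        """Flow at fixed (x, t-array) for a single theta, with the exact
        Jacobian d flow / d theta (used by gradient-based samplers)."""
        c = self.ctx[vid]
        t = np.asarray(t, float)
        n = t.size
        x = np.full(n, float(x))
        Theta = np.broadcast_to(np.asarray(Theta1, float), (n, self.space.dim))
        X = self.embed(vid, x, t, Theta, clip=True)
        S = self._theta_tangents(n)
        Y, TY, _ = self.nets[vid].forward(X, S)
        q = c.q_mean + c.q_std * Y[:, 0]
        J = c.q_std * TY[:, :, 0].T  # (n, dim)
        if c.is_root:
            mix = 0.5 * np.pi * x / c.L
            q = np.cos(mix) * self.inflow.qin(t) + np.sin(mix) * q
            J = np.sin(mix)[:, None] * J
        return q, J

    # ------------------------------------------------------------------
    # loss functions: each returns (value, {vid: grads}) over a batch
    # ------------------------------------------------------------------
    def loss_data(self, batch, want_grads=True):
        """Mean squared mismatch with solver midpoint data, in standardised
        units.  batch: {vid: (t, Theta, q_sim, p_sim)}."""
        total = 0.0
        count = 0
        grads = {}
        for vid, (t, Theta, q_sim, p_sim) in batch.items():
            c = self.ctx[vid]
            n = t.size
            x = np.full(n, c.L / 2.0)
            X = self.embed(vid, x, t, Theta)
            Y, _, cache = self.nets[vid].forward(X)
            q = c.q_mean + c.q_std * Y[:, 0]
            p = c.p_mean + c.p_std * Y[:, 1]
            if c.is_root:
                mix = 0.5 * np.pi * x / c.L
                cosx, sinx = np.cos(mix), np.sin(mix)
                q = cosx * self.inflow.qin(t) + sinx * q
            eq = (q - q_sim) / c.q_std
            ep = (p - p_sim) / c.p_std
            total += float((eq**2).sum() + (ep**2).sum())
            count += n
            if want_grads:
                gY = np.empty_like(Y)
                dq = 2.0 * eq / c.q_std
                if c.is_root:
                    dq = dq * sinx
                gY[:, 0] = dq * c.q_std
                gY[:, 1] = 2.0 * ep / c.p_std * c.p_std
                grads[vid] = self.nets[vid].backward(cache, gY)
        value = total / max(count, 1)
        if want_grads:
            for g in grads.values():
                for k in g:
                    g[k] = g[k] / max(count, 1)
        return value, grads

    def loss_bifurcation(self, t, Theta, want_grads=True):
        """Flow conservation and pressure continuity at every junction,
        evaluated at parent outlets and daughter inlets."""
        n = t.size
        total = 0.0
        grads = {}
        per_vessel_g = {}

        # evaluate each vessel's endpoints once
        evals = {}
        for pid, d1, d2 in self.network.junctions:
            for vid, xfrac in ((pid, 1.0), (d1, 0.0), (d2, 0.0)):
                key = (vid, xfrac)
                if key in evals:
                    continue
                c = self.ctx[vid]
                x = np.full(n, xfrac * c.L)
                X = self.embed(vid, x, t, Theta)
                Y, _, cache = self.nets[vid].forward(X)
                q = c.q_mean + c.q_std * Y[:, 0]
                p = c.p_mean + c.p_std * Y[:, 1]
                extra = None
                if c.is_root:
                    mix = 0.5 * np.pi * xfrac
                    q = np.cos(mix) * self.inflow.qin(t) + np.sin(mix) * q
                    extra = np.sin(mix)
                evals[key] = {"q": q, "p": p, "cache": cache, "gY": 0.0,
                              "mixq": extra}

        n_res = 0
        for pid, d1, d2 in self.network.junctions:
            cp = self.ctx[pid]
            ep_ = evals[(pid, 1.0)]
            e1 = evals[(d1, 0.0)]
            e2 = evals[(d2, 0.0)]
            rq = (ep_["q"] - e1["q"] - e2["q"]) / cp.q_std
            rp1 = (ep_["p"] - e1["p"]) / cp.p_std
            rp2 = (ep_["p"] - e2["p"]) / cp.p_std
            total += float((rq**2 + rp1**2 + rp2**2).sum())
            n_res += 3 * n
            if want_grads:
                gq = 2.0 * rq / cp.q_std
                ep_["gY"] = ep_["gY"] + np.column_stack(
                    [gq, 2.0 * (rp1 + rp2) / cp.p_std]
                )
                e1["gY"] = e1["gY"] + np.column_stack(
                    [-gq, -2.0 * rp1 / cp.p_std]
                )
                e2["gY"] = e2["gY"] + np.column_stack(
                    [-gq, -2.0 * rp2 / cp.p_std]
                )
        value = total / max(n_res, 1)
        if want_grads:
            for (vid, _), ev in evals.items():
                if np.ndim(ev["gY"]) == 0:
                    continue
                c = self.ctx[vid]
                gY = ev["gY"].copy()
                gY[:, 0] *= c.q_std
                gY[:, 1] *= c.p_std
                if ev["mixq"] is not None:
                    gY[:, 0] *= ev["mixq"]
                gY /= max(n_res, 1)
                g = self.nets[vid].backward(ev["cache"], gY)
                if vid in per_vessel_g:
                    for k in g:
                        per_vessel_g[vid][k] += g[k]
                else:
                    per_vessel_g[vid] = g
            grads = per_vessel_g
        return value, grads

    def loss_pde(self, pde_batch, want_grads=True):
        """Mass and momentum residuals from exact input derivatives.

        Residuals are nondimensionalised per vessel by q_std/L (mass) and
        q_std/T (momentum) so the loss is comparable across vessels.
        """
        rho = self.base.rho
        nu = self.base.nu
        delta = math.sqrt(nu * self.T / (2.0 * math.pi))
        Cf = 2.0 * math.pi * nu / (delta * math.sqrt(math.pi))
        p0 = self.base.p0
        total = 0.0
        count = 0
        grads = {}
        for vid, (x, t, Theta) in pde_batch.items():
            c = self.ctx[vid]
            n = x.size
            X = self.embed(vid, x, t, Theta)
            S = self._xt_tangents(vid, t, n)
            Y, TY, cache = self.nets[vid].forward(X, S)
            q = c.q_mean + c.q_std * Y[:, 0]
            p = c.p_mean + c.p_std * Y[:, 1]
            qx = c.q_std * TY[0, :, 0]
            qt = c.q_std * TY[1, :, 0]
            px = c.p_std * TY[0, :, 1]
            pt = c.p_std * TY[1, :, 1]
            if c.is_root:
                mix = 0.5 * np.pi * x / c.L
                cosx, sinx = np.cos(mix), np.sin(mix)
                dmix = 0.5 * np.pi / c.L
                qin = self.inflow.qin(t)
                dqin = self.inflow.dqin_dt(t)
                qx = -dmix * sinx * qin + dmix * cosx * q + sinx * qx
                qt = cosx * dqin + sinx * qt
                q = cosx * qin + sinx * q

            f = self._f_wall(vid, Theta)
            kap0 = 3.0 * c.A0 / (2.0 * f)  # dA/dp at zero strain / bracket
            bracket = 3.0 * (p - p0) / (4.0 * f) + 1.0
            bracket = np.maximum(bracket, 1e-3)
            A = c.A0 * bracket**2
            kappa = kap0 * bracket  # dA/dp
            dkap_dp = kap0 * 3.0 / (4.0 * f)
            At = kappa * pt
            Ax = kappa * px

            r1 = At + qx
            u = q / A
            r2 = (
                qt
                + 2.0 * u * qx
                - u * u * Ax
                + (A / rho) * px
                + Cf * q / np.sqrt(A)
            )
            s1 = c.q_std / c.L
            s2 = c.q_std / self.T
            total += float(((r1 / s1) ** 2 + (r2 / s2) ** 2).sum())
            count += n
            if want_grads:
                w1 = 2.0 * r1 / s1**2
                w2 = 2.0 * r2 / s2**2
                # partials of r1, r2 wrt (q, p, qx, qt, px, pt)
                dA = (
                    -2.0 * u * qx / A
                    + 2.0 * u * u * Ax / A
                    + px / rho
                    - 0.5 * Cf * q * A ** (-1.5)
                )
                d_q = w2 * (2.0 * qx / A - 2.0 * u * Ax / A + Cf / np.sqrt(A))
                d_p = (
                    w1 * dkap_dp * pt
                    + w2 * (dA * kappa - u * u * dkap_dp * px)
                )
                d_qx = w1 + w2 * 2.0 * u
                d_qt = w2
                d_px = w2 * (-u * u * kappa + A / rho)
                d_pt = w1 * kappa
                if c.is_root:
                    # chain through the inflow mixing
                    d_q_net = (
                        d_q * sinx + d_qx * dmix * cosx
                    )
                    d_qx_net = d_qx * sinx
                    d_qt_net = d_qt * sinx
                else:
                    d_q_net = d_q
                    d_qx_net = d_qx
                    d_qt_net = d_qt
                gY = np.empty_like(Y)
                gY[:, 0] = d_q_net * c.q_std
                gY[:, 1] = d_p * c.p_std
                gTY = np.empty_like(TY)
                gTY[0, :, 0] = d_qx_net * c.q_std
                gTY[1, :, 0] = d_qt_net * c.q_std
                gTY[0, :, 1] = d_px * c.p_std
                gTY[1, :, 1] = d_pt * c.p_std
                g = self.nets[vid].backward(cache, gY, gTY)
                grads[vid] = g
        value = total / max(count, 1)
        if want_grads:
            for g in grads.values():
                for k in g:
                    g[k] = g[k] / max(count, 1)
        return value, grads

    def loss_outflow(self, coll: CollocationSet, want_grads=True):
        """Mismatch between predicted terminal pressure and the convolution
        of predicted terminal flow with the precomputed impedance kernels."""
        tj = coll.imp_times
        m = tj.size
        total = 0.0
        grads = {}
        n_design = coll.imp_theta.shape[0]
        count = 0
        for vid, mats in coll.imp_conv.items():
            c = self.ctx[vid]
            accum = None
            for i in range(n_design):
                theta = coll.imp_theta[i]
                Theta = np.broadcast_to(theta, (m, self.space.dim))
                x = np.full(m, c.L)
                X = self.embed(vid, x, tj, Theta)
                Y, _, cache = self.nets[vid].forward(X)
                q = c.q_mean + c.q_std * Y[:, 0]
                p = c.p_mean + c.p_std * Y[:, 1]
                mixq = None
                if c.is_root:
                    mix = 0.5 * np.pi
                    q = math.cos(mix) * self.inflow.qin(tj) + math.sin(mix) * q
                    mixq = math.sin(mix)
                C = mats[i]
                pc = C @ q
                e = (p - (self.base.p0 + pc)) / c.p_std
                total += float((e**2).sum())
                count += m
                if want_grads:
                    gY = np.empty_like(Y)
                    gq = -(C.T @ (2.0 * e / c.p_std))
                    if mixq is not None:
                        gq = gq * mixq
                    gY[:, 0] = gq * c.q_std
                    gY[:, 1] = (2.0 * e / c.p_std) * c.p_std
                    g = self.nets[vid].backward(cache, gY)
                    if accum is None:
                        accum = g
                    else:
                        for k in g:
                            accum[k] += g[k]
            if want_grads and accum is not None:
                grads[vid] = accum
        value = total / max(count, 1)
        if want_grads:
            for g in grads.values():
                for k in g:
                    g[k] = g[k] / max(count, 1)
        return value, grads

    # ------------------------------------------------------------------
    @staticmethod
    def _grad_norm(grads):
        s = 0.0
        for g in grads.values():
            for v in g.values():
                s += float((np.asarray(v) ** 2).sum())
        return math.sqrt(s)

    def update_weights(self, norms: dict[str, float], gamma: float):
        """Gradient-norm balancing: lambda_i,new = sum_j ||g_j|| / ||g_i||,
        blended by exponential moving average."""
        active = {k: v for k, v in norms.items() if v > 0}
        if not active:
            return
        tot = sum(active.values())
        for k in active:
            lam_new = tot / active[k]
            self.loss_weights[k] = (
                gamma * self.loss_weights[k] + (1.0 - gamma) * lam_new
            )

    def train(
        self,
        dataset=None,
        coll: CollocationSet | None = None,
        config: TrainConfig | None = None,
    ):
        """Adam with cosine-decayed learning rate on the weighted total loss.

        ``dataset`` supplies midpoint simulator data (may be None in
        data-free mode); ``coll`` supplies physics collocation inputs (may
        be None in data-only mode).
        """
        cfg = config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        use_phys = cfg.mode in ("pinn", "physics_only") and coll is not None
        use_data = cfg.mode in ("pinn", "data_only") and dataset is not None
        if not use_phys and not use_data:
            raise ValueError("nothing to train on")
        vids = list(self.nets)
        opt = Adam([self.nets[v] for v in vids], lr=cfg.lr0)

        def sub_pde():
            out = {}
            for vid, (x, t, Th) in coll.pde.items():
                idx = rng.integers(0, x.size, size=min(cfg.batch_pde, x.size))
                out[vid] = (x[idx], t[idx], Th[idx])
            return out

        def sub_bif():
            nb = coll.bif_t.size
            idx = rng.integers(0, nb, size=min(cfg.batch_bif, nb))
            return coll.bif_t[idx], coll.bif_theta[idx]

        def sub_data():
            out = {}
            for vid in vids:
                t, Th, qs, ps = dataset.flat_batch(vid)
                idx = rng.integers(0, t.size, size=min(cfg.batch_data, t.size))
                out[vid] = (t[idx], Th[idx], qs[idx], ps[idx])
            return out

        has_junc = len(self.network.junctions) > 0
        for step in range(cfg.steps):
            lr = cosine_lr(step, cfg.steps, cfg.lr0, cfg.lr_min)
            comp = {}
            if use_phys:
                comp["pde"] = self.loss_pde(sub_pde())
                if has_junc:
                    comp["bif"] = self.loss_bifurcation(*sub_bif())
                comp["imp"] = self.loss_outflow(coll)
            if use_data:
                comp["sim"] = self.loss_data(sub_data())

            if (
                len(comp) > 1
                and cfg.weight_update_every
                and step % cfg.weight_update_every == 0
            ):
                norms = {k: self._grad_norm(g) for k, (_, g) in comp.items()}
                self.update_weights(norms, cfg.gamma)

            total_grads = [dict() for _ in vids]
            loss_val = 0.0
            for name, (val, gdict) in comp.items():
                lam = self.loss_weights[name] if len(comp) > 1 else 1.0
                loss_val += lam * val
                for i, vid in enumerate(vids):
                    if vid in gdict:
                        for k, g in gdict[vid].items():
                            if k in total_grads[i]:
                                total_grads[i][k] = total_grads[i][k] + lam * g
                            else:
                                total_grads[i][k] = lam * g
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite training loss at step {step}"
                )
            opt.step(total_grads, lr=lr)
            if step % cfg.log_every == 0 or step == cfg.steps - 1:
                self.history["loss"].append(
                    {"step": step, "total": loss_val,
                     **{k: v[0] for k, v in comp.items()}}
                )
                self.history["weights"].append(
                    {"step": step, **dict(self.loss_weights)}
                )
        return self.history

    def polish_lbfgs(
        self,
        dataset=None,
        coll: CollocationSet | None = None,
        maxiter: int = 300,
        n_pde_full: int = 1024,
        seed: int = 0,
    ):
        """Full-batch L-BFGS refinement of the weighted total loss.

        Mini-batch Adam stalls on the stiff composite PINN objective long
        before the residuals reach their floor; a deterministic full-batch
        quasi-Newton polish with the loss weights frozen at their current
        values drives them much lower.  Uses fixed sub-samples of the
        collocation sets so the objective is deterministic.
        """
        from scipy.optimize import minimize

        rng = np.random.default_rng(seed)
        vids = list(self.nets)
        lam = dict(self.loss_weights)
        use_phys = coll is not None
        use_data = dataset is not None

        pde_fix = None
        if use_phys:
            pde_fix = {}
            for vid, (x, t, Th) in coll.pde.items():
                idx = rng.choice(x.size, min(n_pde_full, x.size), replace=False)
                pde_fix[vid] = (x[idx], t[idx], Th[idx])
        data_fix = None
        if use_data:
            data_fix = {vid: dataset.flat_batch(vid) for vid in vids}

        sizes = [self.nets[v].get_flat().size for v in vids]
        splits = np.cumsum(sizes)[:-1]

        def unpack(z):
            for v, part in zip(vids, np.split(z, splits)):
                self.nets[v].set_flat(part)

        def obj(z):
            unpack(z)
            comp = {}
            if use_phys:
                comp["pde"] = self.loss_pde(pde_fix)
                if self.network.junctions:
                    comp["bif"] = self.loss_bifurcation(
                        coll.bif_t, coll.bif_theta
                    )
                comp["imp"] = self.loss_outflow(coll)
            if use_data:
                comp["sim"] = self.loss_data(data_fix)
            val = 0.0
            gtot = [None] * len(vids)
            for name, (v, gd) in comp.items():
                w = lam[name] if len(comp) > 1 else 1.0
                val += w * v
                for i, vid in enumerate(vids):
                    if vid in gd:
                        flat = np.concatenate(
                            [
                                np.asarray(gd[vid][k]).ravel()
                                for k in self.nets[vid].param_names()
                            ]
                        )
                        gtot[i] = (
                            w * flat if gtot[i] is None else gtot[i] + w * flat
                        )
            g = np.concatenate(
                [
                    gi if gi is not None else np.zeros(s)
                    for gi, s in zip(gtot, sizes)
                ]
            )
            return val, g

        z0 = np.concatenate([self.nets[v].get_flat() for v in vids])
        res = minimize(
            obj,
            z0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "maxcor": 50},
        )
        unpack(res.x)
        self.history["loss"].append(
            {"step": -1, "total": float(res.fun), "lbfgs_nit": int(res.nit)}
        )
        return res

    # -- checkpointing -------------------------------------------------
    def topology_hash(self) -> str:
        import hashlib

        desc = repr(
            sorted(
                (v.id, round(v.length_L, 9), round(v.radius_r0, 9),
                 tuple(v.daughters))
                for v in self.network.vessels.values()
            )
        ) + repr(self.space.names)
        return hashlib.sha256(desc.encode()).hexdigest()[:16]

    def save_checkpoint(self, path):
        blobs = {"_hash": np.frombuffer(
            self.topology_hash().encode(), dtype=np.uint8
        )}
        for vid, net in self.nets.items():
            blobs[f"net{vid}"] = net.get_flat()
            c = self.ctx[vid]
            blobs[f"stats{vid}"] = np.array(
                [c.q_mean, c.q_std, c.p_mean, c.p_std]
            )
        np.savez(path, **blobs)

    def load_checkpoint(self, path, strict=True):
        """Restore weights and normalisation.  With ``strict=False`` a
        checkpoint from a different (e.g. perturbed) geometry is accepted,
        which is the warm-start entry point for transfer learning."""
        data = np.load(path)
        if strict and bytes(data["_hash"]).decode() != self.topology_hash():
            raise ValueError(
                "checkpoint was trained against a different vascular "
                "network or parameter space"
            )
        for vid, net in self.nets.items():
            net.set_flat(data[f"net{vid}"])
            c = self.ctx[vid]
            c.q_mean, c.q_std, c.p_mean, c.p_std = data[f"stats{vid}"]


def make_collocation(
    emu: NetworkEmulator,
    n_pde: int = 2048,
    n_bif: int = 512,
    n_imp: int = 8,
    m_imp: int = 32,
    kernels_by_theta=None,
    seed: int = 0,
) -> CollocationSet:
    """Sample collocation inputs: uniform in x and t, Latin hypercube in
    theta; impedance kernels are precomputed per design point.

    ``kernels_by_theta``: list of (theta, {vid: ImpedanceKernel}) for the
    outflow design; if omitted, kernels are built on the fly.
    """
    from scipy.stats import qmc

    from .solver import build_kernels

    rng = np.random.default_rng(seed)
    space = emu.space
    T = emu.T

    def lhs(n, seed_off):
        s = qmc.LatinHypercube(d=space.dim, seed=seed + seed_off)
        return space.denormalise(s.random(n))

    pde = {}
    for vid in emu.nets:
        c = emu.ctx[vid]
        x = rng.uniform(0.0, c.L, n_pde)
        t = rng.uniform(0.0, T, n_pde)
        pde[vid] = (x, t, lhs(n_pde, 1 + vid))
    bif_t = rng.uniform(0.0, T, n_bif)
    bif_theta = lhs(n_bif, 777)

    if kernels_by_theta is None:
        thetas = lhs(n_imp, 999)
        kernels_by_theta = []
        for th in thetas:
            params = space.update_params(emu.base, th)
            kernels_by_theta.append(
                (th, build_kernels(emu.network, params, max(m_imp, 64)))
            )
    imp_theta = np.array([th for th, _ in kernels_by_theta])
    imp_conv = {vid: [] for vid in emu.network.terminal_ids}
    for _, kd in kernels_by_theta:
        for vid in imp_conv:
            imp_conv[vid].append(conv_matrix(kd[vid], m_imp))
    imp_times = np.arange(m_imp) * (T / m_imp)
    return CollocationSet(
        pde=pde,
        bif_t=bif_t,
        bif_theta=bif_theta,
        imp_theta=imp_theta,
        imp_conv=imp_conv,
        imp_times=imp_times,
    )
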