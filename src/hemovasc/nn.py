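"""Feed-forward network machinery for the physics-informed emulator.

Implements tanh multilayer perceptrons with three switchable variants used
in PINN practice: the base MLP, the "modified MLP" (two input-encoder
streams U, V mixed into every hidden state, h <- (1-z) U + z V), and random
weight factorisation (RWF; each weight matrix parametrised as
diag(exp(s)) V with s ~ N(0.5, 0.1) at initialisation).

PDE residual losses need derivatives of the outputs with respect to network
*inputs* as well as gradients with respect to the *weights* of losses built
from those derivatives.  ``forward`` therefore propagates forward-mode
tangents along a set of input directions together with the activations, and
``backward`` is the hand-derived reverse pass through that joint
computation: it accepts cotangents for both the outputs and the output
tangents and returns exact weight gradients.  The implementation is plain
numpy; correctness is pinned against finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ArchSpec", "MLP", "Adam", "cosine_lr", "count_parameters"]


@dataclass(frozen=True)
class ArchSpec:
    """Architecture of one per-vessel network.

    ``depth`` counts hidden layers (the first maps in_dim -> width); the
    linear output layer is bias-free, the counting convention under which a
    13-input, 5x128 base network has exactly 68,096 trainable scalars.
    """

    in_dim: int
    width: int = 128
    depth: int = 5
    out_dim: int = 2
    modified: bool = False
    rwf: bool = False

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("need at least one hidden layer")


def count_parameters(spec: ArchSpec, breakdown: bool = False):
    """Exact trainable-scalar count for an architecture.

    The base path counts biased hidden layers plus the bias-free linear
    output; encoder streams (modified MLP) and RWF scale vectors are counted
    separately and included in the total.
    """
    w, d = spec.width, spec.depth
    base = (spec.in_dim * w + w) + (d - 1) * (w * w + w) + w * spec.out_dim
    encoders = 2 * (spec.in_dim * w + w) if spec.modified else 0
    rwf_scales = 0
    if spec.rwf:
        # one scale per output row of every weight matrix
        rwf_scales = d * w + spec.out_dim + (2 * w if spec.modified else 0)
    total = base + encoders + rwf_scales
    if breakdown:
        return {
            "base": base,
            "encoders": encoders,
            "rwf_scales": rwf_scales,
            "total": total,
        }
    return total


def _glorot(rng, n_out, n_in):
    lim = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_out, n_in))


class MLP:
    """One tanh network with optional modified-MLP mixing and RWF weights.

    Parameters live in ``self.params`` (name -> ndarray); weight matrices
    are materialised through :meth:`weight` so RWF stays transparent to the
    forward/backward passes.
    """

    def __init__(self, spec: ArchSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        shapes = [("W0", spec.width, spec.in_dim)]
        shapes += [
            (f"W{l}", spec.width, spec.width) for l in range(1, spec.depth)
        ]
        shapes += [("Wout", spec.out_dim, spec.width)]
        if spec.modified:
            shapes += [
                ("Wu", spec.width, spec.in_dim),
                ("Wv", spec.width, spec.in_dim),
            ]
        for name, n_out, n_in in shapes:
            W = _glorot(rng, n_out, n_in)
            if spec.rwf:
                s = 0.5 + 0.1 * rng.standard_normal(n_out)
                self.params["s_" + name] = s
                self.params["V_" + name] = W / np.exp(s)[:, None]
            else:
                self.params[name] = W
        for l in range(spec.depth):
            self.params[f"b{l}"] = np.zeros(spec.width)
        if spec.modified:
            self.params["bu"] = np.zeros(spec.width)
            self.params["bv"] = np.zeros(spec.width)

    # -- RWF-transparent weight access -------------------------------------
    def weight(self, name):
        if self.spec.rwf:
            return np.exp(self.params["s_" + name])[:, None] * self.params[
                "V_" + name
            ]
        return self.params[name]

    def _accumulate_weight_grad(self, grads, name, gW):
        if self.spec.rwf:
            s = self.params["s_" + name]
            V = self.params["V_" + name]
            W = np.exp(s)[:, None] * V
            grads["V_" + name] = grads.get("V_" + name, 0) + np.exp(s)[
                :, None
            ] * gW
            grads["s_" + name] = grads.get("s_" + name, 0) + (gW * W).sum(1)
        else:
            grads[name] = grads.get(name, 0) + gW

    # -- forward -----------------------------------------------------------
    def forward(self, X, tangents=None):
        """Evaluate the network, optionally with forward-mode tangents.

        X: (N, in_dim); tangents: (K, N, in_dim) input directions.
        Returns (Y, TY, cache) with Y (N, out_dim) and TY (K, N, out_dim)
        (TY is None when no tangents are given).
        """
        spec = self.spec
        K = 0 if tangents is None else tangents.shape[0]
        S = tangents
        cache = {"X": X, "S": S, "layers": []}

        if spec.modified:
            for nm, key in (("u", "Wu"), ("v", "Wv")):
                W = self.weight(key)
                E = np.tanh(X @ W.T + self.params["b" + nm])
                mE = None
                SE = None
                if K:
                    mE = S @ W.T
                    SE = (1.0 - E**2) * mE
                cache[nm] = (E, mE, SE)

        a = X
        Sa = S
        for l in range(spec.depth):
            W = self.weight(f"W{l}")
            z = a @ W.T + self.params[f"b{l}"]
            t = np.tanh(z)
            mt = St = None
            if K:
                mt = Sa @ W.T
                St = (1.0 - t**2) * mt
            if spec.modified and l > 0:
                U, _, SU = cache["u"]
                V, _, SV = cache["v"]
                h = (1.0 - t) * U + t * V
                Sh = None
                if K:
                    Sh = St * (V - U) + (1.0 - t) * SU + t * SV
            else:
                h = t
                Sh = St
            cache["layers"].append((a, Sa, t, mt, St))
            a, Sa = h, Sh

        Wo = self.weight("Wout")
        Y = a @ Wo.T
        TY = Sa @ Wo.T if K else None
        cache["a_last"] = a
        cache["S_last"] = Sa
        return Y, TY, cache

    # -- backward ----------------------------------------------------------
    def backward(self, cache, gY, gTY=None):
        """Weight gradients of a scalar that depends on outputs (cotangent
        gY) and output tangents (cotangents gTY, shape (K, N, out_dim))."""
        spec = self.spec
        S = cache["S"]
        K = 0 if S is None else S.shape[0]
        if gTY is None and K:
            gTY = np.zeros((K,) + gY.shape)
        grads: dict[str, np.ndarray] = {}

        a = cache["a_last"]
        Sa = cache["S_last"]
        Wo = self.weight("Wout")
        gWo = gY.T @ a
        if K:
            for k in range(K):
                gWo += gTY[k].T @ Sa[k]
        self._accumulate_weight_grad(grads, "Wout", gWo)
        gh = gY @ Wo
        gSh = gTY @ Wo if K else None

        gU = gV = gSU = gSV = None
        if spec.modified:
            U, _, SU = cache["u"]
            V, _, SV = cache["v"]
            gU = np.zeros_like(U)
            gV = np.zeros_like(V)
            if K:
                gSU = np.zeros_like(SU)
                gSV = np.zeros_like(SV)

        for l in range(spec.depth - 1, -1, -1):
            a_prev, S_prev, t, mt, St = cache["layers"][l]
            if spec.modified and l > 0:
                U, _, SU = cache["u"]
                V, _, SV = cache["v"]
                # h = (1-t) U + t V
                gt = gh * (V - U)
                gU += gh * (1.0 - t)
                gV += gh * t
                gSt = None
                if K:
                    gSt = gSh * (V - U)
                    for k in range(K):
                        gU -= gSh[k] * St[k]
                        gV += gSh[k] * St[k]
                        gSU[k] += gSh[k] * (1.0 - t)
                        gSV[k] += gSh[k] * t
                        gt += gSh[k] * (SV[k] - SU[k])
            else:
                gt = gh
                gSt = gSh
            # t = tanh(a_prev W^T + b), St = (1-t^2) * (S_prev W^T)
            if K:
                for k in range(K):
                    gt = gt - 2.0 * t * mt[k] * gSt[k]
            gz = (1.0 - t**2) * gt
            W = self.weight(f"W{l}")
            gW = gz.T @ a_prev
            if K:
                gmt = (1.0 - t**2) * gSt
                for k in range(K):
                    gW += gmt[k].T @ S_prev[k]
            grads[f"b{l}"] = grads.get(f"b{l}", 0) + gz.sum(0)
            self._accumulate_weight_grad(grads, f"W{l}", gW)
            gh = gz @ W
            if K:
                gSh = gmt @ W

        if spec.modified:
            X = cache["X"]
            for nm, key, gE, gSE in (
                ("u", "Wu", gU, gSU),
                ("v", "Wv", gV, gSV),
            ):
                E, mE, SE = cache[nm]
                if K:
                    for k in range(K):
                        gE = gE - 2.0 * E * mE[k] * gSE[k]
                gz = (1.0 - E**2) * gE
                W = self.weight(key)
                gW = gz.T @ X
                if K:
                    gm = (1.0 - E**2) * gSE
                    for k in range(K):
                        gW += gm[k].T @ S[k]
                grads["b" + nm] = grads.get("b" + nm, 0) + gz.sum(0)
                self._accumulate_weight_grad(grads, key, gW)
        return grads

    # -- flat-vector helpers ----------------------------------------------
    def param_names(self):
        return sorted(self.params)

    def get_flat(self):
        return np.concatenate(
            [self.params[n].ravel() for n in self.param_names()]
        )

    def set_flat(self, vec):
        i = 0
        for n in self.param_names():
            sz = self.params[n].size
            self.params[n] = vec[i : i + sz].reshape(self.params[n].shape)
            i += sz

    @property
    def n_params(self):
        return sum(p.size for p in self.params.values())


class Adam:
    """Adam optimiser over a list of parameter dicts (one per network)."""

    def __init__(self, nets, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.nets = nets
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [
            {n: np.zeros_like(p) for n, p in net.params.items()}
            for net in nets
        ]
        self.v = [
            {n: np.zeros_like(p) for n, p in net.params.items()}
            for net in nets
        ]

    def step(self, grads_per_net, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for net, grads, m, v in zip(self.nets, grads_per_net, self.m, self.v):
            for n, g in grads.items():
                m[n] = b1 * m[n] + (1 - b1) * g
                v[n] = b2 * v[n] + (1 - b2) * g * g
                net.params[n] = net.params[n] - lr * (m[n] / bc1) / (
                    np.sqrt(v[n] / bc2) + self.eps
                )


def cosine_lr(step, n_steps, lr0=1e-3, lr_min=1e-4):
    """Cosine decay from lr0 to lr_min over n_steps."""
    if n_steps <= 1:
        return lr_min
    frac = min(max(step / (n_steps - 1), 0.0), 1.0)
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * frac))
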