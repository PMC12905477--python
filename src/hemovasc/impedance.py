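"""Structured-tree outflow impedance.

The small-vessel bed attached to each terminal vessel is a self-similar
binary tree.  In every small vessel the linearised momentum/continuity
equations admit a frequency-domain solution, so the input impedance
Z(0, w) of a vessel follows from the impedance Z(L, w) at its outlet; at a
bifurcation daughter input impedances combine in parallel.  Propagating from
the leaves (terminal impedance zero) to the root yields the root impedance
Z_root(w_k) at the harmonics w_k = 2*pi*k/T, whose inverse Fourier transform
is the convolution kernel relating terminal flow history to pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .network import BiophysicalParams, StructuredTreeSpec, stiffness_law

__all__ = [
    "ImpedanceKernel",
    "womersley_factor",
    "vessel_impedance",
    "tree_root_impedance",
    "outflow_pressure",
]

_MAX_DEPTH = 200  # alpha,beta < 1 guarantees termination well before this


@dataclass
class ImpedanceKernel:
    """Root impedance of one structured tree over one cardiac period.

    ``Z_root[k]`` is the impedance at angular frequency 2*pi*k/T for
    k = 0..m-1 (conjugate-symmetric), ``z_time`` the real time-domain kernel
    with the convention that Dt * (circular convolution of flow samples with
    ``z_time``) approximates the continuous periodic convolution.
    """

    frequencies: np.ndarray
    Z_root: np.ndarray
    z_time: np.ndarray
    period_T: float
    m: int
    root_radius: float

    @property
    def dc_impedance(self) -> float:
        return float(self.Z_root[0].real)


def womersley_factor(omega, r0, nu):
    """Bessel-function factor F_J = 2 J1(w0) / (w0 J0(w0)).

    w0 = i^{3/2} * r0 * sqrt(omega/nu) is the complex Womersley argument.
    The small-argument series limit (F_J -> 1 as omega -> 0) is used below
    |w0| = 1e-4.
    """
    scalar = np.ndim(omega) == 0
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(omega < 0) or r0 <= 0 or nu <= 0:
        raise ValueError("need omega >= 0, r0 > 0, nu > 0")
    w0 = 1j**1.5 * r0 * np.sqrt(omega / nu)
    out = np.empty(w0.shape, dtype=complex)
    aw = np.abs(w0)
    small = aw < 1e-4
    # Bessel evaluation overflows once Im(w0) ~ 700; J1/J0 -> i there, so
    # switch to the asymptotic tail F_J ~ 2i/w0 well before that point.
    large = aw > 600.0
    mid = ~small & ~large
    out[small] = 1.0 + w0[small] ** 2 / 8.0  # 2J1/(wJ0) = 1 + w^2/8 + O(w^4)
    wm = w0[mid]
    out[mid] = 2.0 * jv(1, wm) / (wm * jv(0, wm))
    out[large] = 2.0j / w0[large]
    return complex(out[0]) if scalar else out


def vessel_impedance(Z_L, omega, *, r0, Eh_over_r0, rho, nu, lrr):
    """Input impedance of one small vessel given its outlet impedance.

    Vectorised over ``omega`` (and matching ``Z_L``).  The w=0 entry uses the
    Poiseuille relation Z(0) = 8*mu*lrr/(pi*r0^3) + Z_L; w != 0 uses the
    travelling-wave solution with compliance C = 3*A0/(2*Eh/r0), wave speed
    c = sqrt(A0*(1-F_J)/(rho*C)) and admittance factor
    g = sqrt(C*A0*(1-F_J)/rho) (principal branches).
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    Z_L = np.atleast_1d(np.asarray(Z_L, dtype=complex)) * np.ones_like(omega)
    A0 = np.pi * r0**2
    L = lrr * r0
    mu = rho * nu
    C = 3.0 * A0 / (2.0 * Eh_over_r0)

    out = np.empty_like(Z_L)
    zero = omega == 0.0
    if np.any(zero):
        out[zero] = 8.0 * mu * lrr / (np.pi * r0**3) + Z_L[zero]
    nz = ~zero
    if np.any(nz):
        w = omega[nz]
        FJ = womersley_factor(w, r0, nu)
        one_m = 1.0 - FJ
        c = np.sqrt(A0 * one_m / (rho * C))
        g = np.sqrt(C * A0 * one_m / rho)
        kl = w * L / c
        s, cs = np.sin(kl), np.cos(kl)
        num = 1j * s / g + Z_L[nz] * cs
        den = cs + 1j * g * Z_L[nz] * s
        bad = np.abs(den) < 1e-300
        if np.any(bad):
            raise FloatingPointError(
                f"impedance resonance at frequency indices "
                f"{np.nonzero(nz)[0][bad].tolist()}"
            )
        out[nz] = num / den
    return out


def tree_root_impedance(
    tree: StructuredTreeSpec,
    params: BiophysicalParams,
    root_radius: float,
    m: int = 512,
    group: int = 0,
    alpha: float | None = None,
) -> ImpedanceKernel:
    """Root impedance kernel of a structured tree over m harmonics.

    Subtrees rooted at equal radius are identical, so results are memoised on
    the exponent pair (i, j) with r = alpha^i * beta^j * root_radius.  A
    vessel bifurcates only if both daughters stay at or above rmin; otherwise
    it terminates with outlet impedance zero.
    """
    if m % 2:
        raise ValueError("m must be even")
    alpha = params.alpha if alpha is None else alpha
    beta, lrr, rmin = tree.beta, tree.lrr, tree.rmin
    if root_radius < rmin:
        # degenerate: treat the root itself as a single terminal vessel
        pass
    T = params.period_T
    omega = 2.0 * np.pi * np.arange(m // 2 + 1) / T
    rho, nu = params.rho, params.nu
    memo: dict[tuple[int, int], np.ndarray] = {}

    def Z0(i: int, j: int, depth: int) -> np.ndarray:
        if depth > _MAX_DEPTH:
            raise RecursionError("structured tree failed to terminate")
        key = (i, j)
        if key in memo:
            return memo[key]
        r = alpha**i * beta**j * root_radius
        if alpha**(i + 1) * beta**j * root_radius >= rmin and (
            alpha**i * beta**(j + 1) * root_radius >= rmin
        ):
            zd1 = Z0(i + 1, j, depth + 1)
            zd2 = Z0(i, j + 1, depth + 1)
            Z_L = zd1 * zd2 / (zd1 + zd2)  # parallel junction condition
        else:
            Z_L = np.zeros_like(omega, dtype=complex)
        f = params.small_vessel_stiffness(r, group)
        val = vessel_impedance(
            Z_L, omega, r0=r, Eh_over_r0=f, rho=rho, nu=nu, lrr=lrr
        )
        memo[key] = val
        return val

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(10000)
    try:
        Z_half = Z0(0, 0, 0)
    finally:
        sys.setrecursionlimit(old)

    Z = np.empty(m, dtype=complex)
    Z[: m // 2 + 1] = Z_half
    Z[m // 2] = Z_half[m // 2].real  # Nyquist bin must be real
    Z[m // 2 + 1 :] = np.conj(Z_half[1 : m // 2][::-1])
    dt = T / m
    z_time = np.fft.ifft(Z) / dt
    resid = np.max(np.abs(z_time.imag)) / max(np.max(np.abs(z_time)), 1e-300)
    if resid > 1e-10:
        raise FloatingPointError("kernel not real after symmetric completion")
    full_omega = 2.0 * np.pi * np.arange(m) / T
    return ImpedanceKernel(
        frequencies=full_omega,
        Z_root=Z,
        z_time=z_time.real,
        period_T=T,
        m=m,
        root_radius=root_radius,
    )


def outflow_pressure(q_history: np.ndarray, kernel: ImpedanceKernel) -> np.ndarray:
    """Terminal pressure over one period from the periodic convolution
    p(L, t) = int q(L, t - tau) z(tau) dtau, evaluated spectrally."""
    q = np.asarray(q_history, dtype=float)
    if q.shape != (kernel.m,):
        raise ValueError(
            f"flow history length {q.shape} does not match kernel m={kernel.m}"
        )
    return np.fft.ifft(np.fft.fft(q) * kernel.Z_root).real
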