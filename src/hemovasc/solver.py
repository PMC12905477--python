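"""High-fidelity 1D haemodynamics solver.

Integrates cross-sectionally averaged mass and momentum balance

    dA/dt + dq/dx = 0
    dq/dt + d/dx(q^2/A) + (A/rho) dp/dx = -(2 pi nu R / delta) (q/A)

on a network of compliant vessels with the linear wall law closing the
system, a prescribed periodic inflow at the root, Newton-solved
flow-conservation/pressure-continuity at bifurcations, and structured-tree
impedance convolution at terminal vessels.  delta = sqrt(nu T / 2 pi) is the
Stokes boundary-layer thickness.

The scheme is the two-step (Richtmyer) Lax-Wendroff method on the
conservative form with flux (q, q^2/A + B(A)), B = 4 f A^{3/2}/(9 rho
sqrt(A0)); boundaries are closed by Riemann-invariant extrapolation
(w+- = u +- 4c, c = sqrt(2f/3rho) (A/A0)^{1/4}).  Cardiac cycles repeat,
with each cycle's terminal pressure computed by convolving the previous
cycle's flow history with the impedance kernel, until the pressure field is
periodic to within ``cycle_tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .impedance import ImpedanceKernel, outflow_pressure, tree_root_impedance
from .network import BiophysicalParams, VascularNetwork

__all__ = [
    "SolverConfig",
    "HemoField",
    "SolverError",
    "simulate",
    "build_kernels",
    "sample_midpoint",
    "mass_conservation_error",
]


class SolverError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    nodes_per_cm: float = 2.0
    time_steps_per_period: int = 256  # output samples m per period
    cfl_safety: float = 0.8
    max_cycles: int = 40
    cycle_tol: float = 1e-3
    min_nodes: int = 7
    internal_steps: int | None = None  # override CFL-derived step count


@dataclass
class HemoField:
    """Flow/pressure/area of one vessel on an (m time) x (n nodes) grid."""

    vessel_id: int
    x_grid: np.ndarray  # (n,)
    t_grid: np.ndarray  # (m,)
    q: np.ndarray  # (m, n) mL/s
    p: np.ndarray  # (m, n) barye gauge
    A: np.ndarray  # (m, n) cm^2


@dataclass
class SimResult:
    fields: dict[int, HemoField]
    converged: bool
    n_cycles: int
    config: SolverConfig
    params: BiophysicalParams


# ---------------------------------------------------------------------------
# numba core
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _advance_cycle(
    A,
    q,
    offs,
    nn,
    dx,
    A0v,
    fv,
    rho,
    nu,
    delta,
    dt,
    n_steps,
    root,
    q_in_steps,
    junc,
    term_vid,
    zt,
    qring,
    g0,
    p0,
    stride,
    Aout,
    qout,
    qterm,
):
    nv = nn.shape[0]
    N = A.shape[0]
    nmax = 0
    for v in range(nv):
        if nn[v] > nmax:
            nmax = nn[v]
    Ah = np.empty(nmax, np.float64)
    qh = np.empty(nmax, np.float64)
    An = np.empty(N, np.float64)
    qn = np.empty(N, np.float64)
    out3 = np.empty(3, np.float64)
    two_pi_nu = 2.0 * np.pi * nu

    for s in range(n_steps):
        if s % stride == 0:
            k = s // stride
            for i in range(N):
                Aout[k, i] = A[i]
                qout[k, i] = q[i]
            for ti in range(term_vid.shape[0]):
                v = term_vid[ti]
                qterm[ti, k] = q[offs[v] + nn[v] - 1]

        # ---- interior Richtmyer update per vessel ----
        for v in range(nv):
            o = offs[v]
            n = nn[v]
            h = dx[v]
            A0 = A0v[v]
            f = fv[v]
            bcoef = 4.0 * f / (9.0 * rho * np.sqrt(A0))
            c0 = np.sqrt(2.0 * f / (3.0 * rho))
            # CFL audit
            lam = dt / h
            for j in range(n):
                Aj = A[o + j]
                if Aj <= 0.0:
                    return 2
                u = q[o + j] / Aj
                c = c0 * (Aj / A0) ** 0.25
                if (abs(u) + c) * lam > 1.0:
                    return 1
            # half step at j+1/2
            for j in range(n - 1):
                Al = A[o + j]
                Ar = A[o + j + 1]
                ql = q[o + j]
                qr = q[o + j + 1]
                F1l = ql
                F1r = qr
                F2l = ql * ql / Al + bcoef * Al * np.sqrt(Al)
                F2r = qr * qr / Ar + bcoef * Ar * np.sqrt(Ar)
                Sl = -two_pi_nu * np.sqrt(Al / np.pi) * ql / (delta * Al)
                Sr = -two_pi_nu * np.sqrt(Ar / np.pi) * qr / (delta * Ar)
                Ah[j] = 0.5 * (Al + Ar) - 0.5 * lam * (F1r - F1l)
                qh[j] = (
                    0.5 * (ql + qr)
                    - 0.5 * lam * (F2r - F2l)
                    + 0.25 * dt * (Sl + Sr)
                )
                if Ah[j] <= 0.0:
                    return 2
            # full step interior nodes
            for j in range(1, n - 1):
                Alh = Ah[j - 1]
                Arh = Ah[j]
                qlh = qh[j - 1]
                qrh = qh[j]
                F2l = qlh * qlh / Alh + bcoef * Alh * np.sqrt(Alh)
                F2r = qrh * qrh / Arh + bcoef * Arh * np.sqrt(Arh)
                Slh = -two_pi_nu * np.sqrt(Alh / np.pi) * qlh / (delta * Alh)
                Srh = -two_pi_nu * np.sqrt(Arh / np.pi) * qrh / (delta * Arh)
                An[o + j] = A[o + j] - lam * (qrh - qlh)
                qn[o + j] = (
                    q[o + j]
                    - lam * (F2r - F2l)
                    + 0.5 * dt * (Slh + Srh)
                )
                if An[o + j] <= 0.0:
                    return 2

        # ---- inflow boundary (root vessel, node 0) ----
        o = offs[root]
        A0 = A0v[root]
        f = fv[root]
        c0 = np.sqrt(2.0 * f / (3.0 * rho))
        qin = q_in_steps[s + 1]
        Anew = A[o]
        for corr in range(2):
            Wm = _boundary_W(
                A[o], q[o], A[o + 1], q[o + 1], A0, c0, nu, delta, -1.0,
                dt, dx[root], Anew, qin, corr,
            )
            Anew = A[o]
            for it in range(40):
                cA = c0 * (Anew / A0) ** 0.25
                phi = qin / Anew - 4.0 * cA - Wm
                dphi = -qin / (Anew * Anew) - cA / Anew
                step = phi / dphi
                Anew -= step
                if Anew <= 0.0:
                    Anew = 0.5 * (Anew + step)  # backtrack
                    if Anew <= 0.0:
                        return 2
                if abs(step) < 1e-14 * A0:
                    break
        An[o] = Anew
        qn[o] = qin

        # ---- junction boundaries ----
        for jj in range(junc.shape[0]):
            vp = junc[jj, 0]
            v1 = junc[jj, 1]
            v2 = junc[jj, 2]
            op = offs[vp] + nn[vp] - 1
            o1 = offs[v1]
            o2 = offs[v2]
            A0p = A0v[vp]
            A01 = A0v[v1]
            A02 = A0v[v2]
            fp = fv[vp]
            f1 = fv[v1]
            f2 = fv[v2]
            c0p = np.sqrt(2.0 * fp / (3.0 * rho))
            c01 = np.sqrt(2.0 * f1 / (3.0 * rho))
            c02 = np.sqrt(2.0 * f2 / (3.0 * rho))
            Ap = A[op]
            A1 = A[o1]
            A2 = A[o2]
            qp = q[op]
            q1 = q[o1]
            q2 = q[o2]
            ok = False
            for corr in range(2):
                # outgoing invariants toward the junction
                Wp = _boundary_W(
                    A[op], q[op], A[op - 1], q[op - 1], A0p, c0p, nu, delta,
                    1.0, dt, dx[vp], Ap, qp, corr,
                )
                W1 = _boundary_W(
                    A[o1], q[o1], A[o1 + 1], q[o1 + 1], A01, c01, nu, delta,
                    -1.0, dt, dx[v1], A1, q1, corr,
                )
                W2 = _boundary_W(
                    A[o2], q[o2], A[o2 + 1], q[o2 + 1], A02, c02, nu, delta,
                    -1.0, dt, dx[v2], A2, q2, corr,
                )
                ok = _solve_junction(
                    Ap, A1, A2, Wp, W1, W2, A0p, A01, A02, fp, f1, f2,
                    c0p, c01, c02, out3,
                )
                if not ok:
                    break
                Ap = out3[0]
                A1 = out3[1]
                A2 = out3[2]
                qp = Ap * (Wp - 4.0 * c0p * (Ap / A0p) ** 0.25)
                q1 = A1 * (W1 + 4.0 * c01 * (A1 / A01) ** 0.25)
                q2 = A2 * (W2 + 4.0 * c02 * (A2 / A02) ** 0.25)
            if not ok or Ap <= 0.0 or A1 <= 0.0 or A2 <= 0.0:
                return 3
            An[op] = Ap
            qn[op] = qp
            An[o1] = A1
            qn[o1] = q1
            An[o2] = A2
            qn[o2] = q2

        # ---- terminal outflow boundaries ----
        # pressure is the discrete periodic convolution of the trailing
        # period of flow history with the impedance kernel, the newest flow
        # sample entering implicitly; solved jointly with the outgoing
        # Riemann invariant by scalar Newton in A.
        m_k = zt.shape[1]
        ring_len = qring.shape[1]
        dtau = dt * stride  # kernel sample spacing T/m
        g = g0 + s + 1  # global step index of the state being built
        for ti in range(term_vid.shape[0]):
            v = term_vid[ti]
            oL = offs[v] + nn[v] - 1
            A0 = A0v[v]
            f = fv[v]
            c0 = np.sqrt(2.0 * f / (3.0 * rho))
            hist = 0.0
            for k in range(1, m_k):
                hist += zt[ti, k] * qring[ti, (g - k * stride) % ring_len]
            hist *= dtau
            z0d = zt[ti, 0] * dtau
            AL = A[oL]
            qL = q[oL]
            ok = False
            for corr in range(2):
                Wp = _boundary_W(
                    A[oL], q[oL], A[oL - 1], q[oL - 1], A0, c0, nu, delta,
                    1.0, dt, dx[v], AL, qL, corr,
                )
                AL = A[oL]
                ok = False
                for it in range(60):
                    cL = c0 * (AL / A0) ** 0.25
                    qL = AL * (Wp - 4.0 * cL)
                    phi = (
                        (4.0 / 3.0) * f * (np.sqrt(AL / A0) - 1.0)
                        - z0d * qL
                        - hist
                    )
                    dphi = (2.0 / 3.0) * f / np.sqrt(AL * A0) - z0d * (
                        Wp - 5.0 * cL
                    )
                    step = phi / dphi
                    AL -= step
                    if AL <= 0.0:
                        return 2
                    if abs(step) < 1e-14 * A0:
                        ok = True
                        break
                if not ok:
                    return 3
                cL = c0 * (AL / A0) ** 0.25
                qL = AL * (Wp - 4.0 * cL)
            An[oL] = AL
            qn[oL] = qL
            qring[ti, g % ring_len] = qL

        for i in range(N):
            A[i] = An[i]
            q[i] = qn[i]
    return 0


@njit(cache=True)
def _solve_junction(
    Ap, A1, A2, Wp, W1, W2, A0p, A01, A02, fp, f1, f2, c0p, c01, c02, out3
):
    """Newton solve of flow conservation + pressure continuity coupled with
    the three outgoing Riemann invariants.  Unknowns are the three areas."""
    for it in range(30):
        cp = c0p * (Ap / A0p) ** 0.25
        c1 = c01 * (A1 / A01) ** 0.25
        c2 = c02 * (A2 / A02) ** 0.25
        F1 = (
            Ap * (Wp - 4.0 * cp)
            - A1 * (W1 + 4.0 * c1)
            - A2 * (W2 + 4.0 * c2)
        )
        pp = (4.0 / 3.0) * fp * (np.sqrt(Ap / A0p) - 1.0)
        p1 = (4.0 / 3.0) * f1 * (np.sqrt(A1 / A01) - 1.0)
        p2 = (4.0 / 3.0) * f2 * (np.sqrt(A2 / A02) - 1.0)
        F2 = pp - p1
        F3 = pp - p2
        a11 = Wp - 5.0 * cp
        a12 = -(W1 + 5.0 * c1)
        a13 = -(W2 + 5.0 * c2)
        dpp = (2.0 / 3.0) * fp / np.sqrt(Ap * A0p)
        dp1 = (2.0 / 3.0) * f1 / np.sqrt(A1 * A01)
        dp2 = (2.0 / 3.0) * f2 / np.sqrt(A2 * A02)
        # J = [[a11 a12 a13], [dpp -dp1 0], [dpp 0 -dp2]]
        det = a11 * dp1 * dp2 + a12 * dpp * dp2 + a13 * dpp * dp1
        if det == 0.0:
            return False
        dAp = (F1 * dp1 * dp2 + a12 * dp2 * F2 + a13 * dp1 * F3) / det
        dA1 = (dpp * dAp - F2) / dp1
        dA2 = (dpp * dAp - F3) / dp2
        Ap -= dAp
        A1 -= dA1
        A2 -= dA2
        if Ap <= 0.0 or A1 <= 0.0 or A2 <= 0.0:
            return False
        if (
            abs(dAp) < 1e-13 * A0p
            and abs(dA1) < 1e-13 * A01
            and abs(dA2) < 1e-13 * A02
        ):
            out3[0] = Ap
            out3[1] = A1
            out3[2] = A2
            return True
    return False


@njit(cache=True, inline="always")
def _boundary_W(Ab, qb, Ai, qi, A0, c0, nu, delta, sign, dt, h, A1, q1, corr):
    """Riemann invariant w = u + sign*4c carried to a boundary node.

    The invariant is interpolated at the foot of the characteristic between
    the boundary node (Ab, qb) and its interior neighbour (Ai, qi) at time n
    and integrated forward with the friction source.  With ``corr`` nonzero,
    (A1, q1) is a predicted boundary state at time n+1 and both the foot
    position and the source use the midpoint rule (second order).
    sign=+1: outgoing w+ at a right boundary (foot speed u + c);
    sign=-1: outgoing w- at a left boundary (foot speed c - u).
    """
    ub = qb / Ab
    cb = c0 * (Ab / A0) ** 0.25
    ui = qi / Ai
    ci = c0 * (Ai / A0) ** 0.25
    xf = (sign * ub + cb) * dt / h
    if xf < 0.0:
        xf = 0.0
    if xf > 1.0:
        xf = 1.0
    if corr:
        u1 = q1 / A1
        c1 = c0 * (A1 / A0) ** 0.25
        uf = ub + (ui - ub) * xf
        cf = cb + (ci - cb) * xf
        xf = 0.5 * ((sign * uf + cf) + (sign * u1 + c1)) * dt / h
        if xf < 0.0:
            xf = 0.0
        if xf > 1.0:
            xf = 1.0
    uf = ub + (ui - ub) * xf
    cf = cb + (ci - cb) * xf
    Af = Ab + (Ai - Ab) * xf
    w = uf + sign * 4.0 * cf
    saf = -2.0 * np.pi * nu * np.sqrt(Af / np.pi) * uf / (delta * Af)
    if corr:
        u1 = q1 / A1
        sa1 = -2.0 * np.pi * nu * np.sqrt(A1 / np.pi) * u1 / (delta * A1)
        w += dt * 0.5 * (saf + sa1)
    else:
        w += dt * saf
    return w


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def build_kernels(
    network: VascularNetwork,
    params: BiophysicalParams,
    m: int,
) -> dict[int, ImpedanceKernel]:
    """Structured-tree impedance kernels for every terminal vessel."""
    out = {}
    for vid in network.terminal_ids:
        v = network.vessels[vid]
        out[vid] = tree_root_impedance(
            v.terminal_tree,
            params,
            root_radius=v.radius_r0,
            m=m,
            group=min(v.group, len(params.f3_small_by_group) - 1),
        )
    return out


def simulate(
    network: VascularNetwork,
    params: BiophysicalParams,
    inflow,
    config: SolverConfig | None = None,
    kernels: dict[int, ImpedanceKernel] | None = None,
) -> SimResult:
    """Run repeated cardiac cycles until the pressure field is periodic.

    ``inflow`` is a callable q(t) in mL/s with period ``params.period_T``.
    Returns the converged final cycle on an m x n grid per vessel.
    """
    config = config or SolverConfig()
    T = params.period_T
    m = config.time_steps_per_period
    if kernels is None:
        kernels = build_kernels(network, params, m)

    vids = network.ordered_ids()
    vidx = {vid: i for i, vid in enumerate(vids)}
    nv = len(vids)
    nn = np.empty(nv, np.int64)
    dx = np.empty(nv)
    A0v = np.empty(nv)
    fv = np.empty(nv)
    for i, vid in enumerate(vids):
        v = network.vessels[vid]
        n = max(config.min_nodes, int(round(v.length_L * config.nodes_per_cm)) + 1)
        nn[i] = n
        dx[i] = v.length_L / (n - 1)
        A0v[i] = v.A0
        fv[i] = params.large_vessel_stiffness(
            v.radius_r0, min(v.group, len(params.f3_large_by_group) - 1)
        )
    offs = np.zeros(nv + 1, np.int64)
    offs[1:] = np.cumsum(nn)
    N = int(offs[-1])

    junc = np.array(
        [[vidx[p], vidx[d1], vidx[d2]] for p, d1, d2 in network.junctions],
        np.int64,
    ).reshape(-1, 3)
    term_ids = network.terminal_ids
    term_vid = np.array([vidx[t] for t in term_ids], np.int64)

    # time step from a conservative wave-speed bound, rounded so that the
    # output stride m divides the internal step count
    rho, nu = params.rho, params.nu
    delta = np.sqrt(nu * T / (2.0 * np.pi))
    if config.internal_steps is None:
        c_bound = np.sqrt(2.0 * fv * 1.4 / (3.0 * rho))
        u_bound = 2.0 * np.abs(
            [inflow(t) for t in np.linspace(0, T, 64)]
        ).max() / A0v.min()
        dt_max = config.cfl_safety * (dx / (c_bound + u_bound)).min()
        n_steps = int(np.ceil(T / dt_max / m)) * m
    else:
        n_steps = int(np.ceil(config.internal_steps / m)) * m
    dt = T / n_steps
    stride = n_steps // m

    t_steps = np.arange(n_steps + 1) * dt
    q_in_steps = np.asarray([inflow(t) for t in t_steps], float)

    A = np.repeat(A0v, nn).astype(float)
    q = np.zeros(N)
    Aout = np.empty((m, N))
    qout = np.empty((m, N))
    qterm = np.zeros((len(term_ids), m))
    zt = np.array([kernels[vid].z_time for vid in term_ids]).reshape(
        len(term_ids), m
    )
    qring = np.zeros((len(term_ids), n_steps))
    t_samp = np.arange(m) * (T / m)

    converged = False
    prev_p = None
    n_cycles = 0
    status = 0
    for cycle in range(config.max_cycles):
        status = _advance_cycle(
            A, q, offs, nn, dx, A0v, fv, rho, nu, delta, dt, n_steps,
            vidx[network.root.id], q_in_steps, junc, term_vid, zt, qring,
            cycle * n_steps, params.p0, stride, Aout, qout, qterm,
        )
        n_cycles = cycle + 1
        if status == 1:
            raise SolverError("CFL violation during integration")
        if status == 2:
            raise SolverError(
                "negative area / wall collapse (parameters outside the "
                "physiological regime)"
            )
        if status == 3:
            raise SolverError("junction Newton iteration failed to converge")
        p_now = np.sqrt(Aout / np.repeat(A0v, nn)[None, :])
        if prev_p is not None:
            scale = max(np.abs(p_now - 1.0).max(), 1e-12)
            rel = np.abs(p_now - prev_p).max() / scale
            if rel < config.cycle_tol:
                converged = True
                break
        prev_p = p_now.copy()
    if not converged and config.cycle_tol > 0:
        warnings.warn(
            f"solver did not reach periodicity in {config.max_cycles} cycles"
        )

    fields = {}
    for i, vid in enumerate(vids):
        v = network.vessels[vid]
        sl = slice(offs[i], offs[i + 1])
        Afield = Aout[:, sl]
        qfield = qout[:, sl]
        pfield = params.p0 + (4.0 / 3.0) * fv[i] * (
            np.sqrt(Afield / A0v[i]) - 1.0
        )
        fields[vid] = HemoField(
            vessel_id=vid,
            x_grid=np.linspace(0.0, v.length_L, nn[i]),
            t_grid=t_samp.copy(),
            q=qfield,
            p=pfield,
            A=Afield,
        )
    return SimResult(
        fields=fields,
        converged=converged,
        n_cycles=n_cycles,
        config=config,
        params=params,
    )


def sample_midpoint(field: HemoField, n_points: int):
    """Flow and pressure at the vessel midpoint at n equidistant times.

    Linear interpolation in x to L/2 and periodic linear interpolation in t.
    Returns (t, q_mid, p_mid).
    """
    m = field.t_grid.size
    if n_points > m:
        raise ValueError("cannot sample more points than the time grid holds")
    T = field.t_grid[1] * m if m > 1 else 1.0
    xm = field.x_grid[-1] / 2.0
    qx = np.array([np.interp(xm, field.x_grid, row) for row in field.q])
    px = np.array([np.interp(xm, field.x_grid, row) for row in field.p])
    t_out = np.arange(n_points) * (T / n_points)
    tg = np.append(field.t_grid, T)
    q_out = np.interp(t_out, tg, np.append(qx, qx[0]))
    p_out = np.interp(t_out, tg, np.append(px, px[0]))
    return t_out, q_out, p_out


def mass_conservation_error(result: SimResult, network: VascularNetwork, inflow):
    """|net inflow volume - total terminal outflow volume| / inflow volume
    over one converged period."""
    root_field = result.fields[network.root.id]
    t = root_field.t_grid
    v_in = np.trapezoid(np.append(root_field.q[:, 0], root_field.q[0, 0]),
                        np.append(t, t[-1] + t[1]))
    v_out = 0.0
    for vid in network.terminal_ids:
        fq = result.fields[vid].q[:, -1]
        v_out += np.trapezoid(np.append(fq, fq[0]), np.append(t, t[-1] + t[1]))
    return abs(v_in - v_out) / abs(v_in)
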