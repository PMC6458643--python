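"""1D pulse-wave propagation solver.

Solves the cross-sectionally averaged mass and momentum equations

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q²/A)/dx + (A/rho) dP/dx = -K_f Q/A

with the tube law ``P = beta (sqrt(A) - sqrt(A0)) / A0`` on every segment of
an arterial tree, using the two-step Lax–Wendroff (Richtmyer) scheme.  The
pressure-gradient term is recast as a conservative flux
``f = beta A^{3/2} / (3 rho A0)`` plus geometric source terms in dA0/dx and
dbeta/dx chosen so that the undisturbed state (A = A0, Q = 0) is an exact
steady solution of a tapered vessel.

Boundary nodes are closed with the characteristic (Riemann) invariants
``W± = u ± 4c`` of the tube law (``c = sqrt(beta/(2 rho A0)) A^{1/4}``):

* junctions enforce flow conservation and static-pressure continuity via a
  Newton solve on the connecting end areas;
* leaves close with an RCR windkessel, a non-reflecting matched condition,
  a closed end (Q = 0), or a reflection-free prescribed state;
* the inlet couples either a prescribed flow Q(t) or the elastance heart
  through an ideal valve with Bernoulli loss.

The friction coefficient ``K_f = 22 pi nu`` corresponds to the polynomial
velocity-profile approximation commonly used for large arteries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .heart import HeartModel
from .tree import MMHG, ArterialTree, WindkesselRCR

__all__ = ["SimResult", "simulate"]


class _Seg:
    """Discretised state of one segment."""

    __slots__ = ("sid", "n", "dx", "a0", "beta", "c0", "k", "da0dx", "dbetadx",
                 "a0h", "betah", "da0dxh", "dbetadxh", "a", "q", "rho", "kf",
                 "f1h_first", "f1h_last")

    def __init__(self, sid: str, geom: dict, rho: float, kf: float) -> None:
        self.sid = sid
        self.a0 = geom["a0"]
        self.beta = geom["beta"]
        self.c0 = geom["c0"]
        self.dx = geom["dx"]
        self.n = self.a0.size
        self.rho = rho
        self.kf = kf
        self.k = np.sqrt(self.beta / (2.0 * rho * self.a0))   # c = k A^{1/4}
        self.da0dx = np.gradient(self.a0, self.dx)
        self.dbetadx = np.gradient(self.beta, self.dx)
        self.a0h = 0.5 * (self.a0[:-1] + self.a0[1:])
        self.betah = 0.5 * (self.beta[:-1] + self.beta[1:])
        self.da0dxh = 0.5 * (self.da0dx[:-1] + self.da0dx[1:])
        self.dbetadxh = 0.5 * (self.dbetadx[:-1] + self.dbetadx[1:])
        self.a = self.a0.copy()
        self.q = np.zeros(self.n)

    # tube law and characteristics -----------------------------------------
    def pressure(self, a: np.ndarray | float, i: int | slice = slice(None)):
        return self.beta[i] * (np.sqrt(a) - np.sqrt(self.a0[i])) / self.a0[i]

    def c(self, a: np.ndarray | float, i: int | slice = slice(None)):
        return self.k[i] * np.asarray(a) ** 0.25

    def flux(self, a, q, a0, beta):
        f1 = q
        f2 = q * q / a + beta * a ** 1.5 / (3.0 * self.rho * a0)
        return f1, f2

    def source2(self, a, q, a0, beta, da0dx, dbetadx):
        s = -self.kf * q / a
        s = s + (beta * da0dx / (self.rho * a0 ** 2)) * (
            (2.0 / 3.0) * a ** 1.5 - 0.5 * a * np.sqrt(a0))
        s = s + (dbetadx / (self.rho * a0)) * (a * np.sqrt(a0)
                                               - (2.0 / 3.0) * a ** 1.5)
        return s

    def lw_step(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Interior Richtmyer update; returns new (A, Q) for nodes 1..n-2."""
        a, q = self.a, self.q
        f1, f2 = self.flux(a, q, self.a0, self.beta)
        s2 = self.source2(a, q, self.a0, self.beta, self.da0dx, self.dbetadx)
        r = dt / self.dx
        ah = 0.5 * (a[:-1] + a[1:]) - 0.5 * r * (f1[1:] - f1[:-1])
        qh = (0.5 * (q[:-1] + q[1:]) - 0.5 * r * (f2[1:] - f2[:-1])
              + 0.25 * dt * (s2[:-1] + s2[1:]))
        f1h, f2h = self.flux(ah, qh, self.a0h, self.betah)
        s2h = self.source2(ah, qh, self.a0h, self.betah, self.da0dxh,
                           self.dbetadxh)
        # boundary half-cell mass fluxes, used to keep boundary nodes
        # conservative after the characteristic solves
        self.f1h_first = float(f1h[0])
        self.f1h_last = float(f1h[-1])
        a_new = a[1:-1] - r * (f1h[1:] - f1h[:-1])
        q_new = (q[1:-1] - r * (f2h[1:] - f2h[:-1])
                 + 0.5 * dt * (s2h[1:] + s2h[:-1]))
        return a_new, q_new


def _char_out_end(seg: _Seg, a, q, dt: float) -> float:
    """Invariant W+ = u + 4c arriving at the distal end after one step.

    Evaluated at the foot of the forward characteristic (linear
    interpolation between the last two nodes of the pre-step state).
    """
    n = seg.n
    u_end = q[n - 1] / a[n - 1]
    lam = u_end + seg.c(a[n - 1], n - 1)
    frac = min(max(lam * dt / seg.dx, 0.0), 1.0)
    w_end = u_end + 4.0 * seg.c(a[n - 1], n - 1)
    w_in = q[n - 2] / a[n - 2] + 4.0 * seg.c(a[n - 2], n - 2)
    return (1.0 - frac) * w_end + frac * w_in


def _char_out_start(seg: _Seg, a, q, dt: float) -> float:
    """Invariant W- = u - 4c arriving at the proximal end after one step."""
    u0 = q[0] / a[0]
    lam = u0 - seg.c(a[0], 0)          # negative for subsonic flow
    frac = min(max(-lam * dt / seg.dx, 0.0), 1.0)
    w0 = u0 - 4.0 * seg.c(a[0], 0)
    w_in = q[1] / a[1] - 4.0 * seg.c(a[1], 1)
    return (1.0 - frac) * w0 + frac * w_in


def _newton_scalar(g, dg, x0: float, lo: float, hi: float, tol: float = 1e-12,
                   max_iter: int = 60) -> float:
    x = x0
    for _ in range(max_iter):
        fx = g(x)
        dfx = dg(x)
        if dfx == 0:
            break
        step = fx / dfx
        x_new = x - step
        if not (lo < x_new < hi):
            x_new = 0.5 * (x + (lo if step > 0 else hi))
        if abs(x_new - x) < tol * max(1.0, abs(x)):
            return x_new
        x = x_new
    return x


@dataclass
class SimResult:
    """Last simulated beat of every segment (node-wise time series)."""

    time: np.ndarray                       # s, within the beat
    dt: float
    series: dict[str, dict[str, np.ndarray]]   # sid -> {"P","Q","A"} (mmHg, ml/s, cm²)
    converged: bool
    converged_beat: int
    root_pp_history: list[float]
    heart: dict = field(default_factory=dict)  # optional V(t), P_v(t) traces

    def node(self, sid: str, i: int) -> dict[str, np.ndarray]:
        s = self.series[sid]
        return {"P": s["P"][:, i], "Q": s["Q"][:, i], "A": s["A"][:, i],
                "U": s["Q"][:, i] / s["A"][:, i]}


def simulate(tree: ArterialTree,
             heart: HeartModel | None = None,
             inflow: Callable[[float], float] | None = None,
             period: float | None = None,
             n_beats: int = 10,
             dt: float | None = None,
             dx: float = 0.5,
             cfl: float = 0.5,
             pp_tol: float = 1e-3,
             store_stride: int = 1,
             warn_on_no_convergence: bool = True) -> SimResult:
    """Run the 1D model until cycle-periodic or for ``n_beats`` beats.

    Exactly one of ``heart`` (elastance ventricle) or ``inflow`` (prescribed
    root flow in ml/s) must be given; ``period`` defaults to the heart
    period and is required with ``inflow``.  Convergence is declared when
    the root pulse pressure changes by less than ``pp_tol`` (relative)
    between consecutive beats.
    """
    import warnings as _warnings

    if (heart is None) == (inflow is None):
        raise ValueError("give exactly one of heart or inflow")
    if period is None:
        if heart is None:
            raise ValueError("period is required with a prescribed inflow")
        period = heart.period

    rho = tree.rho
    kf = 22.0 * np.pi * tree.nu
    segs = {sid: _Seg(sid, s.discretise(dx, rho), rho, kf)
            for sid, s in tree.segments.items()}
    order = list(tree.segments)

    # CFL-limited time step from the undisturbed state (u ~ 100 cm/s headroom)
    limit = min(s.dx / (s.c0.max() + 100.0) for s in segs.values())
    if dt is None:
        dt = cfl * limit
    elif dt > limit:
        raise ValueError(f"dt={dt:g} violates the CFL limit {limit:g}")
    n_steps = int(round(period / dt))
    dt = period / n_steps

    # terminal windkessel states (distal pressure behind Zc), started near
    # the expected working mean to shorten the charging transient
    pc: dict[str, float] = {sid: 85.0 * MMHG for sid in tree.leaves
                            if isinstance(tree.segments[sid].terminal,
                                          WindkesselRCR)}

    # heart state
    if heart is not None:
        vv = heart.initial_volume()
        valve_open = False
        q_av = 0.0

    root = segs[tree.root]

    junctions = [(sid, tree.segments[sid].children) for sid in order
                 if tree.segments[sid].children]

    n_store = (n_steps + store_stride - 1) // store_stride
    series = {sid: {"P": np.empty((n_store, s.n)), "Q": np.empty((n_store, s.n)),
                    "A": np.empty((n_store, s.n))} for sid, s in segs.items()}
    heart_trace = {"V": np.empty(n_store), "P_v": np.empty(n_store)} \
        if heart is not None else {}

    pp_history: list[float] = []
    converged = False
    converged_beat = -1

    def terminal_update(seg: _Seg, term, wp: float) -> tuple[float, float]:
        """Solve the distal boundary; returns (A, Q) at the last node."""
        i = seg.n - 1
        ki = seg.k[i]
        if term == "closed":
            cb = wp / 4.0
            if cb <= 0:
                return seg.a[i], 0.0
            return (cb / ki) ** 4, 0.0
        if term == "matched":
            cb = (wp + 4.0 * seg.c0[i]) / 8.0
            ab = (cb / ki) ** 4
            ub = 4.0 * (cb - seg.c0[i])
            return ab, ab * ub
        # RCR
        zc, rp, cp = term.z_c, term.r_p, term.c_p
        p_old = pc[seg.sid]
        if cp > 0:
            denom = 1.0 + dt / (rp * cp)

            def pc_new(qb: float) -> float:
                return (p_old + dt * qb / cp) / denom

            dpc_dq = (dt / cp) / denom
        else:
            def pc_new(qb: float) -> float:
                return 0.0

            dpc_dq = 0.0
            zc = zc + rp   # pure resistive terminal

        def g(ab: float) -> float:
            ub = wp - 4.0 * ki * ab ** 0.25
            qb = ab * ub
            return seg.pressure(ab, i) - zc * qb - pc_new(qb)

        def dg(ab: float) -> float:
            cb = ki * ab ** 0.25
            ub = wp - 4.0 * cb
            dq = ub - cb
            return rho * cb * cb / ab - (zc + dpc_dq) * dq

        a_guess = seg.a[i]
        ab = _newton_scalar(g, dg, a_guess, 0.05 * seg.a0[i], 20.0 * seg.a0[i])
        ub = wp - 4.0 * ki * ab ** 0.25
        qb = ab * ub
        if cp > 0:
            pc[seg.sid] = pc_new(qb)
        return ab, qb

    t = 0.0
    for beat in range(n_beats):
        for step in range(n_steps):
            # interior update (uses pre-step state); boundary invariants come
            # from the pre-step state as well
            pre = {sid: (s.a.copy(), s.q.copy()) for sid, s in segs.items()}
            for s in segs.values():
                a_new, q_new = s.lw_step(dt)
                s.a[1:-1] = a_new
                s.q[1:-1] = q_new

            t_new = t + dt

            # inlet
            a_pre, q_pre = pre[tree.root]
            wm = _char_out_start(root, a_pre, q_pre, dt)
            k0 = root.k[0]
            if inflow is not None:
                q_target = float(inflow(t_new))

                def g_in(ab: float) -> float:
                    return ab * (wm + 4.0 * k0 * ab ** 0.25) - q_target

                def dg_in(ab: float) -> float:
                    cb = k0 * ab ** 0.25
                    return wm + 4.0 * cb + cb

                ab = _newton_scalar(g_in, dg_in, root.a[0], 0.05 * root.a0[0],
                                    20.0 * root.a0[0])
                root.a[0] = ab
                root.q[0] = q_target
            else:
                # elastance ventricle: fill, update volume, then couple valve
                p_v_old = heart.ventricular_pressure(t, vv)
                q_mv = max(0.0, (heart.p_fill_cgs - p_v_old) / heart.r_mv_cgs)
                vv = vv + dt * (q_mv - q_av)
                p_v = heart.ventricular_pressure(t_new, vv)
                p_root = root.pressure(a_pre[0], 0)
                if not valve_open and p_v > p_root:
                    valve_open = True
                if valve_open:
                    bv = heart.valve_loss

                    def g_h(ab: float) -> float:
                        ub = wm + 4.0 * k0 * ab ** 0.25
                        qb = ab * ub
                        return p_v - bv * qb * abs(qb) - root.pressure(ab, 0)

                    def dg_h(ab: float) -> float:
                        cb = k0 * ab ** 0.25
                        ub = wm + 4.0 * cb
                        qb = ab * ub
                        dq = ub + cb
                        return -2.0 * bv * abs(qb) * dq - rho * cb * cb / ab
                    ab = _newton_scalar(g_h, dg_h, root.a[0],
                                        0.05 * root.a0[0], 20.0 * root.a0[0])
                    ub = wm + 4.0 * k0 * ab ** 0.25
                    qb = ab * ub
                    if qb <= 0.0:
                        valve_open = False
                if not valve_open:
                    # closed valve: Q = 0, area from the incoming invariant
                    cb = -wm / 4.0
                    ab = (cb / k0) ** 4 if cb > 0 else root.a[0]
                    qb = 0.0
                root.a[0] = ab
                root.q[0] = qb
                q_av = qb

            # junctions
            for sid, children in junctions:
                _junction_update(segs[sid], [segs[c] for c in children],
                                 pre, dt)

            # terminals
            for sid in tree.leaves:
                seg = segs[sid]
                pa, pq = pre[sid]
                wp = _char_out_end(seg, pa, pq, dt)
                seg.a[-1], seg.q[-1] = terminal_update(
                    seg, tree.segments[sid].terminal, wp)

            # conservative correction of boundary areas: the characteristic
            # solves fix the boundary flow; the boundary node's area is then
            # set from the half-cell continuity budget so the discrete total
            # mass changes exactly by the net boundary inflow
            for sid, s in segs.items():
                pa, _ = pre[sid]
                half = 0.5 * s.dx
                s.a[0] = pa[0] - dt / half * (s.f1h_first - s.q[0])
                s.a[-1] = pa[-1] - dt / half * (s.q[-1] - s.f1h_last)

            # sanity
            if step % 200 == 0:
                for s in segs.values():
                    if not np.isfinite(s.a).all() or s.a.min() <= 0:
                        raise RuntimeError(
                            f"negative or non-finite area in segment {s.sid} "
                            f"at t={t_new:.4f}s")

            if step % store_stride == 0:
                j = step // store_stride
                for sid, s in segs.items():
                    series[sid]["A"][j] = s.a
                    series[sid]["Q"][j] = s.q
                    series[sid]["P"][j] = s.pressure(s.a) / MMHG
                if heart is not None:
                    heart_trace["V"][j] = vv
                    heart_trace["P_v"][j] = heart.ventricular_pressure(
                        t_new, vv) / MMHG
            t = t_new

        root_p = series[tree.root]["P"][:, 0]
        pp = float(root_p.max() - root_p.min())
        pp_history.append(pp)
        if len(pp_history) >= 2 and pp > 0:
            if abs(pp - pp_history[-2]) < pp_tol * pp:
                converged = True
                converged_beat = beat
                break

    if not converged and warn_on_no_convergence:
        _warnings.warn("1D simulation did not reach cycle-periodicity; "
                       "returning the last beat", stacklevel=2)

    return SimResult(
        time=np.arange(n_store) * dt * store_stride,
        dt=dt * store_stride,
        series=series,
        converged=converged,
        converged_beat=converged_beat,
        root_pp_history=pp_history,
        heart=heart_trace,
    )


def _junction_update(parent: _Seg, children: list[_Seg], pre: dict,
                     dt: float) -> None:
    """Junction Newton solve (flow conservation + static-pressure continuity).

    Characteristic invariants feeding the junction are interpolated at the
    characteristic feet of the pre-step state.
    """
    rho = parent.rho
    ends = [(parent, parent.n - 1, +1.0)] + [(c, 0, -1.0) for c in children]
    w = []
    for seg, i, sign in ends:
        pa, pq = pre[seg.sid]
        if sign > 0:
            w.append(_char_out_end(seg, pa, pq, dt))
        else:
            w.append(_char_out_start(seg, pa, pq, dt))
    a_vec = np.array([pre[seg.sid][0][i] for seg, i, _ in ends])
    m = len(ends)
    a0_vec = np.array([seg.a0[i] for seg, i, _ in ends])
    for _ in range(40):
        u = np.empty(m)
        cc = np.empty(m)
        p = np.empty(m)
        for j, (seg, i, sign) in enumerate(ends):
            cc[j] = seg.k[i] * a_vec[j] ** 0.25
            u[j] = w[j] - 4.0 * cc[j] if sign > 0 else w[j] + 4.0 * cc[j]
            p[j] = seg.pressure(a_vec[j], i)
        q = a_vec * u
        res = np.empty(m)
        res[0] = q[0] - q[1:].sum()
        res[1:] = p[1:] - p[0]
        scale = max(1.0, float(np.abs(q).max()))
        if np.max(np.abs(res[:1])) < 1e-10 * scale and \
                np.max(np.abs(res[1:])) < 1e-8:
            break
        jac = np.zeros((m, m))
        for j, (seg, i, sign) in enumerate(ends):
            dq = u[j] - cc[j] if sign > 0 else u[j] + cc[j]
            dp = rho * cc[j] ** 2 / a_vec[j]
            jac[0, j] = dq if j == 0 else -dq
            if j == 0:
                jac[1:, 0] = -dp
            else:
                jac[j, j] = dp
        try:
            delta = np.linalg.solve(jac, res)
        except np.linalg.LinAlgError:
            break
        a_new = np.maximum(a_vec - delta, 0.05 * a0_vec)
        if np.max(np.abs(a_new - a_vec) / a_vec) < 1e-13:
            a_vec = a_new
            break
        a_vec = a_new
    for j, (seg, i, sign) in enumerate(ends):
        cc_j = seg.k[i] * a_vec[j] ** 0.25
        u_j = w[j] - 4.0 * cc_j if sign > 0 else w[j] + 4.0 * cc_j
        seg.a[i] = a_vec[j]
        seg.q[i] = a_vec[j] * u_j
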