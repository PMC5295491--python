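"""Numba inner loop of the 1-D pulse-wave solver.

Everything here is in SI units (m, s, Pa, m^3/s). The tube law per node is
linear-elastic, P = Pref + (A/A0 - 1)/D, giving a local wave speed
c(A) = sqrt(A / (rho * D * A0)) and Riemann invariants W± = u ± 2c. The
interior scheme is MacCormack (forward-difference predictor,
backward-difference corrector) on

    dA/dt + dQ/dx = -s(x, t)
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx = -Kr Q/A

with Poiseuille friction Kr = 8 pi nu. Boundaries are coupled through the
outgoing characteristic: a time-varying-elastance ventricle behind a diode
valve at the inlet, 3-element windkessels at the outlet and at one interior
branch node (head-and-neck vessels lumped), the latter entering the mass
equation as a sink spread over three nodes.
"""

import numpy as np
from numba import njit

RHO = 1060.0  # kg/m^3
KR = 8.0 * np.pi * 3.8e-6  # Poiseuille friction, m^2/s (nu = mu/rho, mu=4 mPa s)


@njit(cache=True, fastmath=False)
def _inlet_state_flow(W2, A_guess, A0, invDA0, q_in):
    """Inlet state for a prescribed inflow: u - 2c = W2 and A*u = q_in."""
    A = A_guess
    for _ in range(30):
        c = np.sqrt(A * invDA0 / RHO)
        u = W2 + 2.0 * c
        f = A * u - q_in
        df = u + A * (invDA0 / (RHO * c))
        A_new = A - f / df
        if A_new < 0.1 * A0:
            A_new = 0.1 * A0
        if abs(A_new - A) < 1e-14:
            A = A_new
            break
        A = A_new
    return A, q_in


@njit(cache=True, fastmath=False)
def _inlet_state(W2, A_guess, A0, invDA0, pref, p_v, r_valve):
    """Solve for (A, Q) at the inlet node: u - 2c = W2 and Q = valve flow.

    Newton iteration on f(A) = A*(W2 + 2c(A)) - Qv(P(A)); the valve is a
    diode with linear resistance, Qv = max(0, (p_v - P)/r_valve).
    """
    A = A_guess
    for _ in range(30):
        c = np.sqrt(A * invDA0 / RHO)
        u = W2 + 2.0 * c
        p = pref + (A - A0) * invDA0
        qv = (p_v - p) / r_valve
        if qv < 0.0:
            qv = 0.0
            dqv_dA = 0.0
        else:
            dqv_dA = -invDA0 / r_valve
        f = A * u - qv
        df = u + A * (invDA0 / (RHO * c)) - dqv_dA
        step = f / df
        A_new = A - step
        if A_new < 0.1 * A0:
            A_new = 0.1 * A0
        if abs(A_new - A) < 1e-14:
            A = A_new
            break
        A = A_new
    c = np.sqrt(A * invDA0 / RHO)
    return A, A * (W2 + 2.0 * c)


@njit(cache=True, fastmath=False)
def _outlet_state(W1, A_guess, A0, invDA0, pref, pc, r1):
    """Solve for (A, Q) at the outlet node: u + 2c = W1, Q = (P - pc)/r1."""
    A = A_guess
    for _ in range(30):
        c = np.sqrt(A * invDA0 / RHO)
        u = W1 - 2.0 * c
        p = pref + (A - A0) * invDA0
        f = A * u - (p - pc) / r1
        df = u - A * (invDA0 / (RHO * c)) - invDA0 / r1
        A_new = A - f / df
        if A_new < 0.1 * A0:
            A_new = 0.1 * A0
        if abs(A_new - A) < 1e-14:
            A = A_new
            break
        A = A_new
    c = np.sqrt(A * invDA0 / RHO)
    return A, A * (W1 - 2.0 * c)


@njit(cache=True, fastmath=False)
def run_cycle(
    A, Q, A0, invDA0, pref, dx, dt, nsteps, t0, period,
    # heart (SI): elastances Pa/m^3, volumes m^3, resistances Pa s/m^3
    e_min, e_max, t_sys, v0, v_lv0, p_la, r_mv, r_valve,
    # terminal windkessel at outlet
    out_r1, out_r2, out_c, out_pout, pc_out0,
    # branch windkessel (node index jb; r1/r2/c; venous pressure)
    jb, br_r1, br_r2, br_c, br_pout, pc_br0,
    # recording stride
    rec_every,
    # inlet mode: 0 = elastance ventricle + valve, 1 = prescribed inflow
    inlet_mode, inflow,
):
    """Advance one cardiac cycle; returns updated states and root recordings.

    Returns (V_lv, pc_out, pc_br, rootA, rootQ, rootP, vol_in, vol_out,
    vol_br, t_end, A, Q). Root traces are sampled every ``rec_every`` steps.
    """
    n = A.size
    nrec = nsteps // rec_every + 1
    rootA = np.empty(nrec)
    rootQ = np.empty(nrec)
    rootP = np.empty(nrec)
    v_lv = v_lv0
    pc_out = pc_out0
    pc_br = pc_br0
    vol_in = 0.0
    vol_out = 0.0
    vol_br = 0.0

    Ap = np.empty(n)
    Qp = np.empty(n)
    P = np.empty(n)
    Pp = np.empty(n)
    s = np.empty(n)  # mass sink

    irec = 0
    for istep in range(nsteps):
        t = t0 + istep * dt
        tc = t % period
        # elastance activation: squared half-sine over systole
        if tc < t_sys:
            act = np.sin(np.pi * tc / t_sys) ** 2
        else:
            act = 0.0
        elast = e_min + (e_max - e_min) * act
        p_v = elast * (v_lv - v0)

        for i in range(n):
            P[i] = pref[i] + (A[i] - A0[i]) * invDA0[i]

        if istep % rec_every == 0:
            rootA[irec] = A[0]
            rootQ[irec] = Q[0]
            rootP[irec] = P[0]
            irec += 1

        # branch sink, spread over nodes jb-1, jb, jb+1
        q_br = (P[jb] - pc_br) / br_r1
        s[:] = 0.0
        s[jb - 1] = 0.25 * q_br / dx
        s[jb] = 0.5 * q_br / dx
        s[jb + 1] = 0.25 * q_br / dx

        # ---- predictor (forward differences) ----
        for i in range(1, n - 1):
            dQdx = (Q[i + 1] - Q[i]) / dx
            dFdx = (Q[i + 1] * Q[i + 1] / A[i + 1] - Q[i] * Q[i] / A[i]) / dx
            dPdx = (P[i + 1] - P[i]) / dx
            Ap[i] = A[i] - dt * (dQdx + s[i])
            Qp[i] = Q[i] - dt * (dFdx + A[i] / RHO * dPdx + KR * Q[i] / A[i])
        Ap[0] = A[0]
        Qp[0] = Q[0]
        Ap[n - 1] = A[n - 1]
        Qp[n - 1] = Q[n - 1]
        for i in range(n):
            Pp[i] = pref[i] + (Ap[i] - A0[i]) * invDA0[i]

        # ---- corrector (backward differences on predicted state) ----
        for i in range(1, n - 1):
            dQdx = (Qp[i] - Qp[i - 1]) / dx
            dFdx = (Qp[i] * Qp[i] / Ap[i] - Qp[i - 1] * Qp[i - 1] / Ap[i - 1]) / dx
            dPdx = (Pp[i] - Pp[i - 1]) / dx
            Anew = 0.5 * (A[i] + Ap[i] - dt * (dQdx + s[i]))
            Qnew = 0.5 * (
                Q[i] + Qp[i] - dt * (dFdx + Ap[i] / RHO * dPdx + KR * Qp[i] / Ap[i])
            )
            A[i] = Anew
            Q[i] = Qnew

        # ---- inlet boundary ----
        c1 = np.sqrt(A[1] * invDA0[1] / RHO)
        W2 = Q[1] / A[1] - 2.0 * c1
        if inlet_mode == 0:
            A_in, Q_in = _inlet_state(W2, A[0], A0[0], invDA0[0], pref[0], p_v, r_valve)
        else:
            A_in, Q_in = _inlet_state_flow(W2, A[0], A0[0], invDA0[0], inflow[istep])
        A[0] = A_in
        Q[0] = Q_in

        # ---- outlet boundary ----
        c2 = np.sqrt(A[n - 2] * invDA0[n - 2] / RHO)
        W1 = Q[n - 2] / A[n - 2] + 2.0 * c2
        A_out, Q_out = _outlet_state(
            W1, A[n - 1], A0[n - 1], invDA0[n - 1], pref[n - 1], pc_out, out_r1
        )
        A[n - 1] = A_out
        Q[n - 1] = Q_out

        # ---- lumped states ----
        q_mv = (p_la - p_v) / r_mv
        if q_mv < 0.0:
            q_mv = 0.0
        v_lv += dt * (q_mv - Q_in)
        pc_out += dt * (Q_out - (pc_out - out_pout) / out_r2) / out_c
        pc_br += dt * (q_br - (pc_br - br_pout) / br_r2) / br_c

        vol_in += dt * Q_in
        vol_out += dt * Q_out
        vol_br += dt * q_br

        # blow-up guard
        if not np.isfinite(A[0]) or A[0] <= 0.0:
            return (v_lv, pc_out, pc_br, rootA[:irec], rootQ[:irec], rootP[:irec],
                    np.nan, np.nan, np.nan, t0 + (istep + 1) * dt, A, Q)

    return (v_lv, pc_out, pc_br, rootA[:irec], rootQ[:irec], rootP[:irec],
            vol_in, vol_out, vol_br, t0 + nsteps * dt, A, Q)
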