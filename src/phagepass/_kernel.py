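"""Inner Runge–Kutta loop of the delay integrator.

Written as a flat scalar loop so it can be JIT-compiled with numba when
available; the plain-Python function is used otherwise (identical numerics,
just slower).  The loop writes the new samples directly into the
preallocated history arrays and the trajectory output arrays.

Status codes: 0 ok, 1 non-finite state, 2 negative density beyond the
roundoff clamp.
"""

from __future__ import annotations

import numpy as np


def _rk4_loop_impl(
    hB, hP,            # history arrays, capacity >= j0 + n_steps + 1
    j0,                # index of the initial sample in the history arrays
    B, BI, P,          # initial state (P modified in place)
    phi, beta, delta,  # per-type parameters
    m,                 # per-type lag in grid steps (int64)
    h, n_steps,
    out_B, out_BI, out_P, out_lag,
    clamp_tol,
):
    k = P.shape[0]
    max_seen = B if B > BI else BI
    for i in range(k):
        if P[i] > max_seen:
            max_seen = P[i]

    L0 = np.empty(k)
    L1 = np.empty(k)
    Lm = np.empty(k)
    p1 = np.empty(k)
    p2 = np.empty(k)
    p3 = np.empty(k)
    dP1 = np.empty(k)
    dP2 = np.empty(k)
    dP3 = np.empty(k)
    dP4 = np.empty(k)

    out_B[0] = B
    out_BI[0] = BI
    for i in range(k):
        out_P[i, 0] = P[i]
        idx = j0 - m[i]
        out_lag[i, 0] = hB[idx] * hP[i, idx] if idx >= 0 else 0.0

    for s in range(n_steps):
        j = j0 + s
        for i in range(k):
            idx = j - m[i]
            if idx >= 0:
                L0[i] = hB[idx] * hP[i, idx]
                L1[i] = hB[idx + 1] * hP[i, idx + 1]
                Lm[i] = (0.5 * (hB[idx] + hB[idx + 1])) * (0.5 * (hP[i, idx] + hP[i, idx + 1]))
            else:
                L0[i] = 0.0
                L1[i] = 0.0
                Lm[i] = 0.0

        # stage 1
        inf = 0.0
        lys = 0.0
        for i in range(k):
            inf += phi[i] * P[i] * B
            lys += phi[i] * L0[i]
        dB1 = -inf
        dBI1 = inf - lys
        for i in range(k):
            dP1[i] = beta[i] * phi[i] * L0[i] - phi[i] * (B + BI) * P[i] - delta[i] * P[i]

        # stage 2
        b = B + 0.5 * h * dB1
        bi = BI + 0.5 * h * dBI1
        for i in range(k):
            p1[i] = P[i] + 0.5 * h * dP1[i]
        inf = 0.0
        lys = 0.0
        for i in range(k):
            inf += phi[i] * p1[i] * b
            lys += phi[i] * Lm[i]
        dB2 = -inf
        dBI2 = inf - lys
        for i in range(k):
            dP2[i] = beta[i] * phi[i] * Lm[i] - phi[i] * (b + bi) * p1[i] - delta[i] * p1[i]

        # stage 3
        b = B + 0.5 * h * dB2
        bi = BI + 0.5 * h * dBI2
        for i in range(k):
            p2[i] = P[i] + 0.5 * h * dP2[i]
        inf = 0.0
        lys = 0.0
        for i in range(k):
            inf += phi[i] * p2[i] * b
            lys += phi[i] * Lm[i]
        dB3 = -inf
        dBI3 = inf - lys
        for i in range(k):
            dP3[i] = beta[i] * phi[i] * Lm[i] - phi[i] * (b + bi) * p2[i] - delta[i] * p2[i]

        # stage 4
        b = B + h * dB3
        bi = BI + h * dBI3
        for i in range(k):
            p3[i] = P[i] + h * dP3[i]
        inf = 0.0
        lys = 0.0
        for i in range(k):
            inf += phi[i] * p3[i] * b
            lys += phi[i] * L1[i]
        dB4 = -inf
        dBI4 = inf - lys
        for i in range(k):
            dP4[i] = beta[i] * phi[i] * L1[i] - phi[i] * (b + bi) * p3[i] - delta[i] * p3[i]

        B += (h / 6.0) * (dB1 + 2.0 * dB2 + 2.0 * dB3 + dB4)
        BI += (h / 6.0) * (dBI1 + 2.0 * dBI2 + 2.0 * dBI3 + dBI4)
        for i in range(k):
            P[i] += (h / 6.0) * (dP1[i] + 2.0 * dP2[i] + 2.0 * dP3[i] + dP4[i])

        if not (np.isfinite(B) and np.isfinite(BI)):
            return 1, s
        # Cell compartments may undershoot zero by O(h * flux) at the kink
        # where an infected cohort empties (fixed lysis time); allow that
        # much, clamp it, and treat anything larger as a numerical failure.
        lysum = 0.0
        for i in range(k):
            li = L0[i] if L0[i] > L1[i] else L1[i]
            lysum += phi[i] * li
        floor_cells = -(clamp_tol * max_seen + 2.0 * h * (lysum + (-dB1)))
        floor_p = -clamp_tol * max_seen
        if B < floor_cells or BI < floor_cells:
            return 2, s
        if B < 0.0:
            B = 0.0
        if BI < 0.0:
            BI = 0.0
        for i in range(k):
            if not np.isfinite(P[i]):
                return 1, s
            if P[i] < floor_p:
                return 2, s
            if P[i] < 0.0:
                P[i] = 0.0
            if P[i] > max_seen:
                max_seen = P[i]
        if B > max_seen:
            max_seen = B
        if BI > max_seen:
            max_seen = BI

        hB[j + 1] = B
        out_B[s + 1] = B
        out_BI[s + 1] = BI
        for i in range(k):
            hP[i, j + 1] = P[i]
            out_P[i, s + 1] = P[i]
            idx = j + 1 - m[i]
            out_lag[i, s + 1] = hB[idx] * hP[i, idx] if idx >= 0 else 0.0

    return 0, n_steps


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    rk4_loop = njit(cache=True)(_rk4_loop_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    rk4_loop = _rk4_loop_impl
    HAVE_NUMBA = False
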