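"""Shared fixtures and the independent brute-force oracle.

The oracle re-integrates the delay system with a plain explicit-Euler loop
written directly from the model equations, sharing no code with the
production integrator.
"""

from __future__ import annotations

import numpy as np
import pytest

from phagepass.core_model import ANCESTOR, PhageParams


def euler_oracle(
    params: list[PhageParams],
    B0: float,
    P0: np.ndarray,
    duration: float,
    h: float = 1e-3,
    BI0: float = 0.0,
    n_transfers: int = 1,
    carryover: float | None = None,
    fresh_B: float | None = None,
):
    """Explicit-Euler reference solution; returns per-transfer (t, B, BI, P) arrays.

    With ``carryover`` set, applies a fractional-carryover reset between
    transfers (phage history scaled by the fraction, fresh hosts).
    """
    k = len(params)
    phi = np.array([p.phi for p in params])
    beta = np.array([p.beta for p in params])
    delta = np.array([p.delta for p in params])
    m = np.array([int(round(p.tau / h)) for p in params])
    n_steps = int(round(duration / h))

    hB: list[float] = []
    hP: list[np.ndarray] = []
    B, BI, P = float(B0), float(BI0), np.asarray(P0, dtype=float).copy()
    transfers = []
    for tr in range(n_transfers):
        tb = np.empty(n_steps + 1)
        tbi = np.empty(n_steps + 1)
        tp = np.empty((k, n_steps + 1))
        for s in range(n_steps):
            j = len(hB)
            hB.append(B)
            hP.append(P.copy())
            tb[s], tbi[s] = B, BI
            tp[:, s] = P
            lag = np.array([
                hB[j - m[i]] * hP[j - m[i]][i] if j - m[i] >= 0 else 0.0
                for i in range(k)
            ])
            inf = phi * B * P
            lys = phi * lag
            newB = max(B + h * (-inf.sum()), 0.0)
            newBI = max(BI + h * (inf.sum() - lys.sum()), 0.0)
            newP = np.maximum(P + h * (beta * lys - phi * (B + BI) * P - delta * P), 0.0)
            B, BI, P = newB, newBI, newP
        tb[-1], tbi[-1] = B, BI
        tp[:, -1] = P
        t = h * np.arange(n_steps + 1)
        transfers.append((t, tb, tbi, tp))
        if tr + 1 < n_transfers and carryover is not None:
            hB.append(B)
            hP.append(P.copy())
            f = carryover
            hP = [p * f for p in hP]
            P = P * f
            BI = BI * f
            B = fresh_B if fresh_B is not None else B0
            hB[-1] = B
            hB.pop()
            hP.pop()
    return transfers


@pytest.fixture(scope="session")
def ancestor() -> PhageParams:
    return ANCESTOR


@pytest.fixture(scope="session")
def short_regime_run():
    """Six 30-min transfers, 2% carryover, ancestral genotype alone."""
    from phagepass.regimes import RegimeConfig, run_regime

    cfg = RegimeConfig(
        transfer_duration=30.0, n_transfers=6, reset_mode="fractional_carryover",
        carryover_fraction=0.02, fresh_B=1e8, initial_P=(1e7,),
    )
    return cfg, run_regime(cfg, [ANCESTOR])
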