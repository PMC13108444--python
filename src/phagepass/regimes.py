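"""Serial-transfer protocols built on the delay-model integrator.

Two reset modes are supported.

``pfu_reset`` (long-transfer protocol): at each transfer end the free phage
are harvested, infected cells are discarded (chloroform extraction kills
them), and the next transfer is seeded on fresh hosts with a fixed total
inoculum (default 1e7 PFU/ml, i.e. input MOI 0.1 on 1e8 cells/ml),
preserving the end-of-transfer genotype composition.  The lysis history is
cleared: no progeny appear until one lysis time into the new transfer.

``fractional_carryover`` (short-transfer protocol): a fixed fraction
(default 2%, a 50-fold dilution) of the whole co-culture — free phage and
infected cells alike — is diluted into fresh hosts.  Carried infected cells
lyse on their original schedule at diluted density, which the integrator
realizes by scaling the stored phage history by the carryover fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core_model import ConfigurationError, PhageParams, SystemState
from .dde_engine import HistoryBuffer, Trajectory, integrate_transfer

__all__ = [
    "RegimeConfig",
    "RegimeResult",
    "ExtinctionError",
    "reset_pfu",
    "reset_fractional",
    "run_regime",
    "LONG_TRANSFER",
    "SHORT_TRANSFER",
]

#: Densities below this (particles or cells per ml) are treated as extinct;
#: guards against denormal noise, far below one particle per culture volume.
EXTINCTION_FLOOR = 1e-12


class ExtinctionError(RuntimeError):
    def __init__(self, transfer_index: int):
        self.transfer_index = transfer_index
        super().__init__(f"total free phage hit zero at transfer {transfer_index}")


@dataclass(frozen=True)
class RegimeConfig:
    """One serial-transfer protocol.

    ``initial_P`` gives the inoculum of the first transfer, per type
    (particles/ml); subsequent transfers are seeded by the reset rule.
    """

    transfer_duration: float
    n_transfers: int
    reset_mode: Literal["pfu_reset", "fractional_carryover"]
    fresh_B: float = 1e8
    reset_pfu: float = 1e7
    carryover_fraction: float = 0.02
    initial_P: tuple[float, ...] = (1e7,)
    step: float = 0.01

    def __post_init__(self) -> None:
        if self.transfer_duration <= 0:
            raise ConfigurationError("transfer_duration must be > 0")
        if self.n_transfers < 1:
            raise ConfigurationError("n_transfers must be >= 1")
        if self.reset_mode not in ("pfu_reset", "fractional_carryover"):
            raise ConfigurationError(f"unknown reset_mode {self.reset_mode!r}")
        if self.reset_mode == "pfu_reset" and self.reset_pfu <= 0:
            raise ConfigurationError("reset_pfu must be > 0 in pfu_reset mode")
        if not (0 < self.carryover_fraction <= 1):
            raise ConfigurationError("carryover_fraction must lie in (0, 1]")
        if self.fresh_B < 0 or any(p < 0 for p in self.initial_P):
            raise ConfigurationError("densities must be >= 0")


#: Canonical long-transfer protocol: 3-h co-culture, chloroform reset to 1e7 PFU/ml.
LONG_TRANSFER = RegimeConfig(
    transfer_duration=180.0, n_transfers=10, reset_mode="pfu_reset",
    fresh_B=1e8, reset_pfu=1e7,
)
#: Canonical short-transfer protocol: 30-min co-culture, 2% carryover.
SHORT_TRANSFER = RegimeConfig(
    transfer_duration=30.0, n_transfers=6, reset_mode="fractional_carryover",
    fresh_B=1e8, carryover_fraction=0.02,
)


@dataclass
class RegimeResult:
    """Per-transfer trajectories plus end-of-transfer titres and genotype frequencies."""

    trajectories: list[Trajectory]
    end_titres: np.ndarray      # (n_transfers, n_types)
    labels: tuple[str, ...]
    frequencies: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        totals = self.end_titres.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.frequencies = np.where(totals > 0, self.end_titres / totals, np.nan)

    @property
    def n_transfers(self) -> int:
        return len(self.trajectories)

    def summary_frame(self):
        import pandas as pd

        rows = []
        for n in range(self.n_transfers):
            row = {"transfer": n + 1}
            for i, lab in enumerate(self.labels):
                row[f"titre_{lab}"] = self.end_titres[n, i]
                row[f"freq_{lab}"] = self.frequencies[n, i]
            rows.append(row)
        return pd.DataFrame(rows)


def _apply_floor(P: np.ndarray) -> np.ndarray:
    P = P.copy()
    P[P < EXTINCTION_FLOOR] = 0.0
    return P


def reset_pfu(
    end_state: SystemState,
    history: HistoryBuffer,
    config: RegimeConfig,
    transfer_index: int = 0,
) -> tuple[SystemState, HistoryBuffer]:
    """Harvest-and-reseed reset: fresh hosts, fixed total phage inoculum,
    composition preserved, infected cells and lysis history discarded."""
    P = _apply_floor(end_state.P)
    total = P.sum()
    if total <= 0:
        raise ExtinctionError(transfer_index)
    new_P = P * (config.reset_pfu / total)
    new_state = SystemState(t=end_state.t, B=config.fresh_B, B_I=0.0, P=new_P)
    new_history = HistoryBuffer(history.n_types, history.step, t0=end_state.t)
    new_history.append(new_state.B, new_state.P)
    return new_state, new_history


def reset_fractional(
    end_state: SystemState,
    history: HistoryBuffer,
    config: RegimeConfig,
    transfer_index: int = 0,
) -> tuple[SystemState, HistoryBuffer]:
    """Dilute the whole co-culture by ``carryover_fraction`` into fresh hosts.

    The stored phage history is scaled by the same fraction so that cells
    infected before the reset lyse on schedule at diluted density; the last
    history node is overwritten with the post-reset state.
    """
    f = config.carryover_fraction
    P = _apply_floor(end_state.P) * f
    new_state = SystemState(t=end_state.t, B=config.fresh_B, B_I=f * end_state.B_I, P=P)
    history.scale_phage(f)
    history.set_last(new_state.B, new_state.P)
    return new_state, history


def run_regime(
    config: RegimeConfig,
    params: Sequence[PhageParams],
) -> RegimeResult:
    """Run the configured serial-transfer protocol.

    Transfer 1 starts from fresh hosts, no infected cells, the configured
    inoculum and empty lysis history; each later transfer starts from the
    configured reset of its predecessor's end state.
    """
    k = len(params)
    initial_P = np.asarray(config.initial_P, dtype=float)
    if initial_P.shape[0] != k:
        raise ConfigurationError(
            f"initial_P has {initial_P.shape[0]} entries for {k} phage types"
        )
    state = SystemState(t=0.0, B=config.fresh_B, B_I=0.0, P=initial_P)
    history = HistoryBuffer(k, config.step, t0=0.0)

    trajectories: list[Trajectory] = []
    end_titres = np.empty((config.n_transfers, k))
    for n in range(config.n_transfers):
        traj, state, history = integrate_transfer(
            state, history, params, config.transfer_duration, config.step
        )
        trajectories.append(traj)
        end_titres[n] = state.P
        if n + 1 < config.n_transfers:
            if config.reset_mode == "pfu_reset":
                state, history = reset_pfu(state, history, config, transfer_index=n + 1)
            else:
                state, history = reset_fractional(state, history, config, transfer_index=n + 1)
    return RegimeResult(trajectories=trajectories, end_titres=end_titres,
                        labels=tuple(p.label for p in params))
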