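"""Core predator–prey model of lytic phage and bacterial host with a fixed lysis delay.

The state tracks uninfected hosts ``B`` (cells/ml), infected hosts ``B_I``
(cells/ml) and one free-phage density ``P_i`` (particles/ml) per phage
genotype.  Infection is irreversible adsorption at a second-order rate
``phi_i * B * P_i``; infected cells lyse exactly ``tau_i`` minutes after
infection, releasing ``beta_i`` progeny, and free phage are lost both to
first-order decay (``delta_i``) and to adsorption onto any cell, infected or
not.  Adsorption onto an already infected cell removes the phage particle
without producing progeny ("unproductive" adsorption).  Host growth within a
transfer is neglected.

The lysed-cell bookkeeping enters through the delayed product
``B(t - tau_i) * P_i(t - tau_i)``; before any history exists the delayed
densities are taken to be zero, so a freshly started culture produces no
progeny until one lysis time has elapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhageParams",
    "SystemState",
    "LaggedValues",
    "ANCESTOR",
    "LARGE_PLAQUE",
    "SMALL_PLAQUE",
    "DEFAULT_TYPES",
    "param_arrays",
    "model_rhs",
    "release_flux",
    "adsorption_split",
]


class ConfigurationError(ValueError):
    """Inconsistent model configuration (mismatched counts, bad step, ...)."""


@dataclass(frozen=True)
class PhageParams:
    """Life-history traits of one phage genotype.

    Parameters
    ----------
    label : str
        Short genotype name.
    phi : float
        Adsorption constant, ml^-1 min^-1 (second-order attachment rate).
    beta : float
        Burst size, progeny particles per lysed cell.
    tau : float
        Lysis time (latent period), min.
    delta : float
        First-order decay rate of free infectious particles, min^-1.
    """

    label: str
    phi: float
    beta: float = 200.0
    tau: float = 17.0
    delta: float = 1.7e-2

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ConfigurationError(f"{self.label}: adsorption constant phi must be >= 0")
        if self.beta < 0:
            raise ConfigurationError(f"{self.label}: burst size beta must be >= 0")
        if self.tau <= 0:
            raise ConfigurationError(f"{self.label}: lysis time tau must be > 0")
        if self.delta < 0:
            raise ConfigurationError(f"{self.label}: decay rate delta must be >= 0")

    def replace(self, **kwargs) -> "PhageParams":
        data = {"label": self.label, "phi": self.phi, "beta": self.beta,
                "tau": self.tau, "delta": self.delta}
        data.update(kwargs)
        return PhageParams(**data)


#: Reference parameterization: ancestral genotype, the slow-adsorbing
#: large-plaque genotype selected under short transfers, and the
#: fast-adsorbing, highly persistent small-plaque genotype selected under
#: long transfers.
ANCESTOR = PhageParams("ancestor", phi=4e-9, beta=200.0, tau=17.0, delta=1.7e-2)
LARGE_PLAQUE = PhageParams("large_plaque", phi=2e-9, beta=200.0, tau=17.0, delta=1.4e-2)
SMALL_PLAQUE = PhageParams("small_plaque", phi=6e-9, beta=200.0, tau=17.0, delta=6e-3)
DEFAULT_TYPES: tuple[PhageParams, ...] = (ANCESTOR, LARGE_PLAQUE, SMALL_PLAQUE)


@dataclass
class SystemState:
    """Instantaneous densities of the host–phage system."""

    t: float
    B: float
    B_I: float
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.B < 0 or self.B_I < 0 or np.any(self.P < 0):
            raise ValueError("densities must be non-negative")

    @property
    def n_types(self) -> int:
        return self.P.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(self.t, self.B, self.B_I, self.P.copy())


@dataclass
class LaggedValues:
    """Delayed products ``B(t - tau_i) * P_i(t - tau_i)`` per genotype.

    ``before_origin`` flags lags that fall before the available history;
    the corresponding product is exactly zero by convention.
    """

    products: np.ndarray
    before_origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.products = np.asarray(self.products, dtype=float)
        if self.before_origin is None:
            self.before_origin = np.zeros(self.products.shape, dtype=bool)
        self.before_origin = np.asarray(self.before_origin, dtype=bool)
        if np.any(self.products < 0):
            raise ValueError("lagged products must be non-negative")
        if np.any(self.products[self.before_origin] != 0.0):
            raise ValueError("pre-origin lagged products must be exactly zero")


def param_arrays(params: Sequence[PhageParams]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-genotype traits into (phi, beta, tau, delta) arrays."""
    if len(params) == 0:
        raise ConfigurationError("at least one phage type is required")
    phi = np.array([p.phi for p in params], dtype=float)
    beta = np.array([p.beta for p in params], dtype=float)
    tau = np.array([p.tau for p in params], dtype=float)
    delta = np.array([p.delta for p in params], dtype=float)
    return phi, beta, tau, delta


def _check_counts(n_state: int, n_params: int) -> None:
    if n_state != n_params:
        raise ConfigurationError(
            f"state carries {n_state} phage types but {n_params} parameter sets were given"
        )


def model_rhs(
    state: SystemState,
    lagged: LaggedValues,
    params: Sequence[PhageParams],
) -> tuple[float, float, np.ndarray]:
    """Right-hand side of the delay system.

    Returns ``(dB/dt, dB_I/dt, dP/dt)`` where ``dP/dt`` is a per-genotype
    array:

    .. math::

        dB/dt   &= -\\Big(\\sum_i \\phi_i P_i\\Big) B \\\\
        dB_I/dt &= \\sum_i \\phi_i (B P_i - [B P_i]_\\tau) \\\\
        dP_i/dt &= \\phi_i (\\beta_i [B P_i]_\\tau - (B + B_I) P_i) - \\delta_i P_i

    with ``[B P_i]_tau`` the delayed product supplied in ``lagged``.
    """
    phi, beta, _, delta = param_arrays(params)
    _check_counts(state.n_types, len(params))
    _check_counts(lagged.products.shape[0], len(params))

    infection = phi * state.B * state.P          # productive adsorption, per type
    lysis = phi * lagged.products                # cells lysing now, per type
    dB = -float(infection.sum())
    dB_I = float(infection.sum() - lysis.sum())
    dP = beta * lysis - phi * (state.B + state.B_I) * state.P - delta * state.P
    return dB, dB_I, dP


def release_flux(lagged: LaggedValues, params: Sequence[PhageParams]) -> np.ndarray:
    """Per-genotype rate of progeny release by lysis, particles ml^-1 min^-1.

    Equals ``phi_i * beta_i * [B P_i]_tau``; zero wherever the lag predates
    the available history.
    """
    phi, beta, _, _ = param_arrays(params)
    _check_counts(lagged.products.shape[0], len(params))
    return phi * beta * lagged.products


def adsorption_split(
    state: SystemState, params: Sequence[PhageParams]
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the adsorption rate into productive and unproductive parts.

    Productive adsorptions hit uninfected cells (``phi_i * B * P_i``) and can
    yield progeny; unproductive ones hit already infected cells
    (``phi_i * B_I * P_i``) and simply remove the particle.  Units:
    events ml^-1 min^-1.
    """
    phi, _, _, _ = param_arrays(params)
    _check_counts(state.n_types, len(params))
    productive = phi * state.B * state.P
    unproductive = phi * state.B_I * state.P
    return productive, unproductive
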