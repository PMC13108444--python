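"""Synthetic assay generators with plaque-count sampling noise.

These emulate the two titre-course assays the estimators consume, so the
full estimation pipeline can be exercised without wet-lab data:

* an adsorption assay — phage mixed with excess hosts at low input MOI
  (default 0.05) and titred at a few early minutes (default 2, 4, 6), within
  the latent period so no progeny confound the decline;
* a persistence assay — a 5-h co-culture at input MOI 0.1, titred every
  30 min, showing a productive rise to a peak followed by exponential decay.

Observed titres are derived from simulated plaque counts: the expected
titre is diluted to a countable range, a Poisson plaque count is drawn, and
the count is converted back to PFU/ml.  All generators are pure functions of
their parameters and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core_model import PhageParams, SystemState
from .dde_engine import HistoryBuffer, integrate_transfer
from .estimators import TitreSeries

__all__ = ["NoiseModel", "gen_plaque_count", "gen_adsorption_assay", "gen_persistence_course"]


@dataclass(frozen=True)
class NoiseModel:
    """Sampling-noise specification for synthetic titres.

    ``poisson_counts`` emulates plaque assays: plate ``plated_volume`` ml of
    a dilution chosen so the expected count falls in ``count_range``, draw a
    Poisson count, convert back to PFU/ml.  ``lognormal`` applies
    multiplicative log-normal noise of scale ``sigma`` (a lighter stand-in
    for count simulation in property tests).  ``none`` returns expectations.
    """

    mode: Literal["none", "poisson_counts", "lognormal"] = "poisson_counts"
    plated_volume: float = 0.1           # ml, as in a standard 100-ul plating
    count_range: tuple[float, float] = (30.0, 300.0)
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be > 0")
        if self.mode not in ("none", "poisson_counts", "lognormal"):
            raise ValueError(f"unknown noise mode {self.mode!r}")


def gen_plaque_count(
    titre: float, dilution: float, plated_volume: float, seed: int | np.random.Generator
) -> int:
    """One simulated plaque count: Poisson with mean titre*volume/dilution."""
    if titre < 0:
        raise ValueError("titre must be >= 0")
    if dilution < 1:
        raise ValueError("dilution must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = titre * plated_volume / dilution
    return int(rng.poisson(mean))


def _auto_dilution(expected_count: float, lo: float, hi: float) -> float:
    """Smallest power-of-ten dilution bringing the expected count below ``hi``.

    Counts already below ``lo`` are plated undiluted: there is no way to
    concentrate a lysate by serial dilution.
    """
    d = 1.0
    while expected_count / d >= hi:
        d *= 10.0
    return d


def _observe(expected: np.ndarray, noise: NoiseModel) -> np.ndarray:
    rng = np.random.default_rng(noise.seed)
    if noise.mode == "none":
        return expected.copy()
    if noise.mode == "lognormal":
        return expected * rng.lognormal(mean=0.0, sigma=noise.sigma, size=expected.shape)
    observed = np.empty_like(expected)
    lo, hi = noise.count_range
    for i, titre in enumerate(expected):
        d = _auto_dilution(titre * noise.plated_volume, lo, hi)
        count = gen_plaque_count(titre, d, noise.plated_volume, rng)
        observed[i] = count * d / noise.plated_volume
    return observed


def gen_adsorption_assay(
    k_true: float,
    B: float,
    P0: float,
    times: Sequence[float] = (2.0, 4.0, 6.0),
    noise: NoiseModel = NoiseModel(mode="none"),
    tau: float = 17.0,
) -> TitreSeries:
    """Synthetic adsorption-assay titre series.

    Expected free-phage titre is ``P0 * exp(-k_true * B * t)``; sampling
    must finish within the latent period so no release occurs.
    """
    if k_true < 0:
        raise ValueError("adsorption constant must be >= 0")
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(times >= tau):
        raise ValueError(
            f"sampling times must lie in (0, {tau}) min: later samples would "
            "include released progeny"
        )
    expected = P0 * np.exp(-k_true * B * times)
    return TitreSeries(times=times, titres=_observe(expected, noise), host_density=B)


def gen_persistence_course(
    params: PhageParams,
    moi: float = 0.1,
    duration: float = 300.0,
    sample_every: float = 30.0,
    noise: NoiseModel = NoiseModel(mode="none"),
    fresh_B: float = 1e8,
    step: float = 0.01,
) -> TitreSeries:
    """Synthetic persistence-assay course from the full delay model.

    Simulates a single uninterrupted co-culture (default 5 h) seeded at the
    input MOI on fresh hosts and samples the free-phage titre at regular
    intervals.  With ancestral-like parameters the series rises through the
    productive phase and then declines at the decay rate once hosts are
    depleted.
    """
    state = SystemState(0.0, fresh_B, 0.0, np.array([moi * fresh_B]))
    traj, _, _ = integrate_transfer(
        state, HistoryBuffer(1, step), [params], duration, step
    )
    times = np.arange(sample_every, duration + step / 2, sample_every)
    idx = np.rint(times / step).astype(int)
    expected = traj.P[0, idx]
    return TitreSeries(
        times=times, titres=_observe(expected, noise), host_density=fresh_B
    )
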