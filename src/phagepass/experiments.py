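"""In-silico evolution experiments on the serial-transfer model.

The experiments probe how the adsorption constant trades off against
unproductive losses under bottlenecked passaging:

* ``single_transfer_competition`` — mutant-vs-ancestor titre ratio after one
  short transfer, swept over mutant adsorption constants; the ratio is
  maximised at an intermediate adsorption constant (slow enough to avoid the
  late-transfer sink of already-infected cells, fast enough to initiate
  infections while hosts are available).
* ``stable_pattern`` / ``detect_bursts`` — the repeating within-transfer
  pattern the carryover regime settles into, with its characteristic burst
  events from overlapping infection cycles.
* ``dilution_decomposition`` — productive vs unproductive adsorption rates
  across dilution factors.
* ``fitness_landscape`` — which adsorption strategy fixes under each
  (transfer time, dilution factor) combination.
* ``robustness_sweep`` — stability of the adsorption optimum against burst
  size and lysis time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .core_model import ANCESTOR, ConfigurationError, PhageParams, SystemState
from .dde_engine import HistoryBuffer, Trajectory, integrate_transfer
from .regimes import RegimeConfig, RegimeResult, reset_fractional, run_regime

__all__ = [
    "BurstEvent",
    "LandscapeCell",
    "CompetitionSweep",
    "OptimumResult",
    "StablePattern",
    "LANDSCAPE_TYPES",
    "competition_ratio",
    "single_transfer_competition",
    "find_optimal_adsorption",
    "free_phage_comparison",
    "stable_pattern",
    "detect_bursts",
    "dilution_decomposition",
    "fitness_landscape",
    "robustness_sweep",
]


# ---------------------------------------------------------------------------
# single-transfer competition and the adsorption optimum


def competition_ratio(
    phi_mutant: float,
    baseline: PhageParams = ANCESTOR,
    moi: float = 0.1,
    duration: float = 30.0,
    fresh_B: float = 1e8,
    step: float = 0.01,
) -> float:
    """Mutant:ancestor free-phage titre ratio after one transfer.

    The two genotypes differ only in adsorption constant and start 1:1 with
    total inoculum ``moi * fresh_B`` on fresh hosts with no prior history.
    """
    params = [baseline, baseline.replace(label="mutant", phi=phi_mutant)]
    p0 = moi * fresh_B / 2.0
    state = SystemState(0.0, fresh_B, 0.0, np.array([p0, p0]))
    _, final, _ = integrate_transfer(
        state, HistoryBuffer(2, step), params, duration, step
    )
    return float(final.P[1] / final.P[0])


@dataclass
class CompetitionSweep:
    phi_grid: np.ndarray
    ratios: np.ndarray
    baseline: PhageParams
    moi: float
    duration: float
    fresh_B: float
    step: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"phi_mutant": self.phi_grid, "titre_ratio": self.ratios})


def single_transfer_competition(
    phi_mutant: Sequence[float] | np.ndarray | None = None,
    baseline: PhageParams = ANCESTOR,
    moi: float = 0.1,
    duration: float = 30.0,
    fresh_B: float = 1e8,
    step: float = 0.01,
) -> CompetitionSweep:
    """Sweep the mutant adsorption constant over 1:1 single-transfer competitions.

    Default grid: 60 log-spaced points from 1000-fold below the ancestral
    adsorption constant up to the ancestral value.
    """
    if phi_mutant is None:
        phi_mutant = np.geomspace(baseline.phi / 1000.0, baseline.phi, 60)
    phi_mutant = np.asarray(phi_mutant, dtype=float)
    if phi_mutant.size == 0:
        raise ConfigurationError("empty adsorption-constant grid")
    ratios = np.array(
        [competition_ratio(p, baseline, moi, duration, fresh_B, step) for p in phi_mutant]
    )
    return CompetitionSweep(phi_mutant, ratios, baseline, moi, duration, fresh_B, step)


@dataclass
class OptimumResult:
    phi_opt: float
    fold_reduction: float        # phi_ancestor / phi_opt
    ratio_at_opt: float
    refined: bool
    at_boundary: bool


def find_optimal_adsorption(
    sweep: CompetitionSweep,
    refine: bool = True,
    objective: Callable[[float], float] | None = None,
) -> OptimumResult:
    """Locate the adsorption constant maximising the competition ratio.

    The grid argmax is refined by a bounded golden-section search between the
    bracketing grid points (1% relative tolerance in phi).  A maximum on the
    grid boundary is returned unrefined with a warning: the optimum is then
    unresolved by the sweep range.
    """
    i = int(np.argmax(sweep.ratios))
    phi_opt = float(sweep.phi_grid[i])
    ratio_opt = float(sweep.ratios[i])
    at_boundary = i == 0 or i == sweep.phi_grid.size - 1
    refined = False
    if at_boundary:
        warnings.warn("competition ratio is maximal at the grid boundary; optimum unresolved")
    elif refine:
        if objective is None:
            objective = lambda phi: competition_ratio(  # noqa: E731
                phi, sweep.baseline, sweep.moi, sweep.duration, sweep.fresh_B, sweep.step
            )
        lo, hi = float(sweep.phi_grid[i - 1]), float(sweep.phi_grid[i + 1])
        res = minimize_scalar(
            lambda p: -objective(p), bounds=(lo, hi), method="bounded",
            options={"xatol": 0.01 * phi_opt},
        )
        phi_opt = float(res.x)
        ratio_opt = float(-res.fun)
        refined = True
    return OptimumResult(
        phi_opt=phi_opt,
        fold_reduction=sweep.baseline.phi / phi_opt,
        ratio_at_opt=ratio_opt,
        refined=refined,
        at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# separate-culture free-phage comparison


def free_phage_comparison(
    params_a: PhageParams,
    params_b: PhageParams,
    config: RegimeConfig,
) -> np.ndarray:
    """End-of-transfer free-phage titre ratio b:a, each genotype passaged alone.

    Raises on extinction of either genotype, reporting the transfer index.
    """
    ratios = []
    results = []
    for p in (params_a, params_b):
        res = run_regime(config, [p])
        for n, titre in enumerate(res.end_titres[:, 0]):
            if titre <= 0:
                raise RuntimeError(f"{p.label} went extinct at transfer {n + 1}")
        results.append(res.end_titres[:, 0])
    ratios = results[1] / results[0]
    return ratios


# ---------------------------------------------------------------------------
# stable within-transfer pattern and burst events


@dataclass
class StablePattern:
    n_converged: int             # -1 when no convergence within the run
    pattern: Trajectory          # transfer n_converged + 1 (or last transfer)
    converged: bool
    diffs: np.ndarray            # sup-norm rel. diff between consecutive transfers
    result: RegimeResult


def _supnorm_reldiff(a: np.ndarray, b: np.ndarray) -> float:
    scale = max(float(a.max()), float(b.max()))
    if scale <= 0:
        return 0.0
    return float(np.abs(a - b).max() / scale)


def stable_pattern(
    config: RegimeConfig,
    params: Sequence[PhageParams],
    tol: float = 0.01,
) -> StablePattern:
    """Find the repeating within-transfer pattern of a serial-transfer run.

    Convergence at transfer ``n`` means the total free-phage trajectory of
    transfer ``n + 1`` matches that of transfer ``n`` within ``tol`` in
    sup-norm relative difference; the reported pattern is transfer
    ``n_converged + 1``.  If no pair converges the last transfer is returned
    with ``converged=False``.
    """
    if config.n_transfers < 3:
        raise ConfigurationError("stable-pattern search needs at least 3 transfers")
    res = run_regime(config, params)
    totals = [traj.P_total for traj in res.trajectories]
    diffs = np.array(
        [_supnorm_reldiff(totals[i], totals[i + 1]) for i in range(len(totals) - 1)]
    )
    for n in range(diffs.size):
        if diffs[n] < tol:
            return StablePattern(n + 1, res.trajectories[n + 1], True, diffs, res)
    return StablePattern(-1, res.trajectories[-1], False, diffs, res)


@dataclass(frozen=True)
class BurstEvent:
    """A lysis burst: a local maximum of the total release flux."""

    time: float                  # min from transfer start
    flux: float                  # particles ml^-1 min^-1


def detect_bursts(
    trajectory: Trajectory,
    params: Sequence[PhageParams],
    threshold_frac: float = 0.01,
) -> list[BurstEvent]:
    """Burst events within one transfer.

    A burst is a strict local maximum of the total release flux exceeding
    ``threshold_frac`` times the transfer's maximal flux.  A plateau (run of
    equal values strictly above both neighbours) yields a single event at the
    run's midpoint grid node.  Events are sorted by time.
    """
    flux = trajectory.release_flux(params).sum(axis=0)
    fmax = float(flux.max())
    if fmax <= 0:
        return []
    t_local = trajectory.t_local
    events: list[BurstEvent] = []
    n = flux.size
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and flux[j + 1] == flux[i]:
            j += 1
        # run [i, j] of equal values; strict local max if both neighbours lower
        if i > 0 and j < n - 1 and flux[i - 1] < flux[i] and flux[j + 1] < flux[i]:
            mid = (i + j) // 2
            if flux[mid] > threshold_frac * fmax:
                events.append(BurstEvent(float(t_local[mid]), float(flux[mid])))
        i = j + 1
    return events


# ---------------------------------------------------------------------------
# productive/unproductive decomposition across dilution factors


def dilution_decomposition(
    dilution_factors: Sequence[float],
    config: RegimeConfig,
    params: Sequence[PhageParams],
    tol: float = 0.01,
):
    """Productive and unproductive adsorption rates over the stable transfer,
    per dilution factor (carryover fraction = 1/dilution).

    Returns a tidy DataFrame with columns ``dilution``, ``time_min``,
    ``productive``, ``unproductive``, ``converged``.
    """
    import pandas as pd

    frames = []
    for d in dilution_factors:
        if d <= 1:
            raise ConfigurationError("dilution factors must exceed 1")
        cfg = dc_replace(config, reset_mode="fractional_carryover",
                         carryover_fraction=1.0 / d)
        sp = stable_pattern(cfg, params, tol=tol)
        if not sp.converged:
            warnings.warn(f"dilution {d}: no convergence within {cfg.n_transfers} transfers")
        prod, unprod = sp.pattern.adsorption_split(params)
        frames.append(pd.DataFrame({
            "dilution": d,
            "time_min": sp.pattern.t_local,
            "productive": prod.sum(axis=0),
            "unproductive": unprod.sum(axis=0),
            "converged": sp.converged,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# transfer-time x dilution fitness landscape


#: Competitors for the landscape: high / intermediate / low adsorption with
#: all other traits shared (ancestral burst size, lysis time and decay).
LANDSCAPE_TYPES: tuple[PhageParams, ...] = (
    PhageParams("high", phi=6e-9, delta=1.7e-2),
    PhageParams("intermediate", phi=4e-9, delta=1.7e-2),
    PhageParams("low", phi=2e-9, delta=1.7e-2),
)


@dataclass
class LandscapeCell:
    transfer_duration: float
    dilution_factor: float
    winner: str | None
    fixed: bool
    frequencies: np.ndarray
    n_transfers_run: int
    failed: bool = False


def fitness_landscape(
    transfer_times: Sequence[float],
    dilution_factors: Sequence[float],
    params: Sequence[PhageParams] = LANDSCAPE_TYPES,
    n_transfers: int = 100,
    fresh_B: float = 1e8,
    total_P0: float = 1e7,
    step: float = 0.01,
    fixation_threshold: float = 0.99,
) -> list[LandscapeCell]:
    """Competition outcome per (transfer time, dilution factor) cell.

    Each cell runs the fractional-carryover regime from equal genotype
    frequencies; the winner is the most frequent genotype at the end, with
    ``fixed`` set when its frequency reaches ``fixation_threshold``.  Cells
    stop early once a genotype exceeds 0.9999 (the map is then decided).
    Numerical failure marks the cell failed and the sweep continues.
    """
    k = len(params)
    cells: list[LandscapeCell] = []
    for T in transfer_times:
        T = round(T / step) * step     # land the duration on the step grid
        for d in dilution_factors:
            if d <= 1:
                raise ConfigurationError("dilution factors must exceed 1")
            f = 1.0 / d
            cfg = RegimeConfig(
                transfer_duration=T, n_transfers=n_transfers,
                reset_mode="fractional_carryover", fresh_B=fresh_B,
                carryover_fraction=f, initial_P=tuple([total_P0 / k] * k),
                step=step,
            )
            try:
                state = SystemState(0.0, fresh_B, 0.0, np.full(k, total_P0 / k))
                history = HistoryBuffer(k, step)
                freqs = np.full(k, 1.0 / k)
                n_run = 0
                for n in range(n_transfers):
                    _, state, history = integrate_transfer(state, history, params, T, step)
                    n_run = n + 1
                    total = state.P.sum()
                    if total > 0:
                        freqs = state.P / total
                    if freqs.max() >= 0.9999:
                        break
                    if n + 1 < n_transfers:
                        state, history = reset_fractional(state, history, cfg, n + 1)
                winner = params[int(np.argmax(freqs))].label if state.P.sum() > 0 else None
                cells.append(LandscapeCell(
                    transfer_duration=T, dilution_factor=d, winner=winner,
                    fixed=bool(freqs.max() >= fixation_threshold),
                    frequencies=freqs, n_transfers_run=n_run,
                ))
            except Exception:
                cells.append(LandscapeCell(
                    transfer_duration=T, dilution_factor=d, winner=None,
                    fixed=False, frequencies=np.full(k, np.nan),
                    n_transfers_run=0, failed=True,
                ))
    return cells


def landscape_frame(cells: list[LandscapeCell]):
    import pandas as pd

    return pd.DataFrame([
        {
            "transfer_duration": c.transfer_duration,
            "dilution_factor": c.dilution_factor,
            "winner": c.winner,
            "fixed": c.fixed,
            "failed": c.failed,
            "n_transfers_run": c.n_transfers_run,
            "max_frequency": float(np.nanmax(c.frequencies)) if not c.failed else np.nan,
        }
        for c in cells
    ])


# ---------------------------------------------------------------------------
# robustness of the optimum to burst size and lysis time


def robustness_sweep(
    beta_grid: Sequence[float],
    tau_grid: Sequence[float],
    baseline: PhageParams = ANCESTOR,
    moi: float = 0.1,
    duration: float = 30.0,
    fresh_B: float = 1e8,
    step: float = 0.01,
    n_phi: int = 25,
):
    """Adsorption-optimum fold reduction per (burst size, lysis time) cell.

    Also reports whether fewer than two infection cycles fit in the transfer
    (``2 * tau > duration``), the condition under which the single-transfer
    optimum is expected to hold.  Returns a tidy DataFrame.
    """
    import pandas as pd

    rows = []
    for beta in beta_grid:
        for tau in tau_grid:
            base = baseline.replace(beta=float(beta), tau=float(tau))
            grid = np.geomspace(base.phi / 1000.0, base.phi, n_phi)
            sweep = single_transfer_competition(
                grid, base, moi=moi, duration=duration, fresh_B=fresh_B, step=step
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                opt = find_optimal_adsorption(sweep)
            rows.append({
                "beta": beta,
                "tau": tau,
                "phi_opt": opt.phi_opt,
                "fold_reduction": opt.fold_reduction,
                "at_boundary": opt.at_boundary,
                "under_two_cycles": 2 * tau > duration,
            })
    return pd.DataFrame(rows)
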