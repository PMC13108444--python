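"""Life-history trait estimators from titre time courses.

Two assay designs are supported:

* adsorption assay — free phage are titred at a few early time points after
  mixing with excess hosts (before any lysis can occur), when the titre
  decays as ``P0 * exp(-k * B * t)``.  The adsorption constant ``k`` is the
  negative slope of an ordinary least-squares fit of log titre against time,
  divided by the (constant) host density.
* persistence assay — a multi-hour co-culture is titred at regular
  intervals; after the productive phase peaks and hosts are depleted, the
  titre declines exponentially at the decay rate ``delta``, estimated by a
  log-linear fit over the post-peak samples.

Natural logarithms are used throughout; the slope estimates are divided
through so both ``k`` and ``delta`` are base-invariant quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = ["TitreSeries", "FitResult", "estimate_adsorption_constant",
           "estimate_decay_rate", "surviving_fraction", "pool_estimates"]


@dataclass
class TitreSeries:
    """Sampled phage titres with their sampling times and host density.

    times are minutes; titres PFU/ml; host_density cells/ml (assumed
    constant over the assay window).
    """

    times: np.ndarray
    titres: np.ndarray
    host_density: float | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.titres = np.asarray(self.titres, dtype=float)
        if self.times.shape != self.titres.shape:
            raise ValueError("times and titres must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.titres < 0):
            raise ValueError("titres must be >= 0")


@dataclass
class FitResult:
    """A single trait estimate with its uncertainty and fit diagnostics."""

    estimate: float
    stderr: float
    window: tuple[float, float]
    n_points: int
    residual_variance: float
    replicate: str | None = None


def _drop_zeros(series: TitreSeries) -> tuple[np.ndarray, np.ndarray]:
    keep = series.titres > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-titre sample(s) from the log fit"
        )
    return series.times[keep], series.titres[keep]


def _loglinear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(y) on t; returns (slope, slope SE, residual variance)."""
    X = sm.add_constant(t)
    fit = sm.OLS(np.log(y), X).fit()
    slope = float(fit.params[1])
    if len(t) > 2:
        se = float(fit.bse[1])
        resid_var = float(fit.mse_resid)
    else:  # exact 2-point fit: no residual degrees of freedom
        se = np.nan
        resid_var = 0.0
    return slope, se, resid_var


def estimate_adsorption_constant(series: TitreSeries) -> FitResult:
    """Adsorption constant ``k`` (ml^-1 min^-1) from an early-timepoint assay.

    ``k = -slope / B`` where slope comes from the OLS fit of log titre vs
    time and ``B`` is the host density; the standard error propagates as
    ``SE(slope) / B``.
    """
    if series.host_density is None or series.host_density <= 0:
        raise ValueError("a positive host density is required to estimate k")
    t, y = _drop_zeros(series)
    if t.size < 2:
        raise ValueError("need at least 2 positive-titre samples")
    slope, se, rv = _loglinear_fit(t, y)
    B = series.host_density
    return FitResult(
        estimate=-slope / B,
        stderr=se / B if np.isfinite(se) else np.nan,
        window=(float(t[0]), float(t[-1])),
        n_points=int(t.size),
        residual_variance=rv,
        replicate=series.replicate,
    )


def estimate_decay_rate(series: TitreSeries) -> FitResult:
    """Decay rate ``delta`` (min^-1) from the post-peak decline of a co-culture.

    The peak is the raw maximum titre sample; the fit covers all samples at
    ``t >= t_peak``.  A monotone-increasing series has no decline period and
    raises; fewer than 3 post-peak points triggers a warning but still fits.
    """
    t, y = _drop_zeros(series)
    if t.size < 2:
        raise ValueError("need at least 2 positive-titre samples")
    ipk = int(np.argmax(y))
    if ipk == t.size - 1:
        raise ValueError("titres peak at the last sample: no decline period to fit")
    tp, yp = t[ipk:], y[ipk:]
    if tp.size < 3:
        warnings.warn("fewer than 3 post-peak samples; decay fit is poorly constrained")
    slope, se, rv = _loglinear_fit(tp, yp)
    return FitResult(
        estimate=-slope,
        stderr=se,
        window=(float(tp[0]), float(tp[-1])),
        n_points=int(tp.size),
        residual_variance=rv,
        replicate=series.replicate,
    )


def surviving_fraction(series: TitreSeries) -> TitreSeries:
    """Titre normalised to the maximum sample: the surviving infectious fraction."""
    if series.titres.size == 0:
        raise ValueError("empty series")
    peak = series.titres.max()
    if peak <= 0:
        raise ValueError("all titres are zero")
    return TitreSeries(
        times=series.times.copy(),
        titres=series.titres / peak,
        host_density=series.host_density,
        replicate=series.replicate,
    )


def pool_estimates(fits: Sequence[FitResult]) -> FitResult:
    """Inverse-variance pooled estimate across replicate fits.

    Replicates without a finite standard error are weighted equally with the
    smallest observed variance.
    """
    if len(fits) == 0:
        raise ValueError("no fits to pool")
    est = np.array([f.estimate for f in fits])
    var = np.array([f.stderr**2 if np.isfinite(f.stderr) else np.nan for f in fits])
    if np.all(np.isnan(var)):
        w = np.ones_like(est)
    else:
        fill = np.nanmin(var[var > 0]) if np.any(var > 0) else 1.0
        var = np.where(np.isnan(var) | (var == 0), fill, var)
        w = 1.0 / var
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w))) if not np.all(w == 1.0) else float(
        np.std(est, ddof=1) / np.sqrt(len(est))
    ) if len(est) > 1 else np.nan
    return FitResult(
        estimate=pooled,
        stderr=pooled_se,
        window=(min(f.window[0] for f in fits), max(f.window[1] for f in fits)),
        n_points=sum(f.n_points for f in fits),
        residual_variance=float(np.mean([f.residual_variance for f in fits])),
    )
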