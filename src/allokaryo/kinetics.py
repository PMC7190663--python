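"""Growth-curve kinetics: maximum specific growth rate from OD time series.

The maximum specific growth rate mu (h^-1) is the steepest slope of
ln(OD) versus time after background subtraction.  The two-point definition
(ln(OD2) - ln(OD1)) / (T2 - T1) is the limit of the estimator used here,
which fits a least-squares line to ln(OD) over every run of
``window_points`` consecutive timepoints and takes the largest slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

OD_EPSILON = 1e-4  # floor for blank-subtracted OD before taking logs

__all__ = ["GrowthCurve", "GrowthRateEstimator", "max_specific_growth_rate"]


@dataclass
class GrowthCurve:
    """OD time series. ``times`` in hours, strictly increasing;
    ``background`` a scalar or per-time series to subtract."""

    times: np.ndarray
    od: np.ndarray
    background: float | np.ndarray = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("OD values must be finite")

    def corrected_od(self) -> np.ndarray:
        return np.maximum(self.od - np.asarray(self.background, dtype=float), OD_EPSILON)


def _coarse_rate(t: np.ndarray, od: np.ndarray) -> float:
    """Crossing-time growth-rate scale: ln(hi/lo) over the time the curve
    takes to rise between two fixed fractions of its dynamic range.  Only
    used to size the fitting window; robust to point noise because it
    depends on two threshold crossings, not local slopes."""
    lo_val = od.min() + 0.05 * np.ptp(od)
    hi_val = od.min() + 0.40 * np.ptp(od)
    above_lo = np.nonzero(od >= lo_val)[0]
    above_hi = np.nonzero(od >= hi_val)[0]
    if above_lo.size == 0 or above_hi.size == 0:
        return 0.0
    t_lo, t_hi = t[above_lo[0]], t[above_hi[0]]
    if t_hi <= t_lo or lo_val <= 0:
        return 0.0
    return float(np.log(hi_val / lo_val) / (t_hi - t_lo))


class GrowthRateEstimator(BaseEstimator):
    """Sliding-window log-linear estimator of the maximum specific growth rate.

    A least-squares line is fit to ln(OD) over every run of consecutive
    timepoints and the steepest slope is mu.  The run length is the larger
    of ``window_points`` and the number of points spanning roughly one
    doubling at a coarse crossing-time rate estimate: for fast growers the
    default 5-point (one hour at 15-min cadence) window applies, while slow
    growers get proportionally longer windows so that measurement noise at
    low OD does not masquerade as growth.

    Parameters
    ----------
    window_points : int
        Minimum number of consecutive timepoints per fit.
    adaptive : bool
        Lengthen the window for slow growers (see above).  Disable to force
        the fixed ``window_points`` window.
    saturation_correction : bool
        When the curve has plateaued, rescale the winning window's slope for
        the logistic suppression accrued across the window (a finite window
        averages slopes at ODs above the inoculum).  Curves still rising at
        the final timepoint are never adjusted.

    Attributes
    ----------
    mu_ : float
        Maximum specific growth rate in h^-1 (negative maxima floored to 0).
    window_points_ : int
        Window length actually used.
    window_start_ : float
        Start time (h) of the winning window.
    flat_ : bool
        True when the curve never rose above background (mu_ forced to 0).
    """

    def __init__(
        self, window_points: int = 5, adaptive: bool = True,
        saturation_correction: bool = True,
    ):
        self.window_points = window_points
        self.adaptive = adaptive
        self.saturation_correction = saturation_correction

    def fit(self, curve: GrowthCurve, y=None) -> "GrowthRateEstimator":
        w = int(self.window_points)
        if w < 2:
            raise ValueError("window_points must be at least 2")
        if curve.times.size < w:
            raise ValueError(
                f"curve has {curve.times.size} points, need at least {w}"
            )
        od = curve.corrected_od()
        self.flat_ = bool(np.all(od <= OD_EPSILON))
        t = curve.times
        if self.adaptive and not self.flat_:
            mu0 = _coarse_rate(t, od)
            if mu0 > 0:
                dt = float(np.median(np.diff(t)))
                # points spanning ~1.5 doublings of log-growth: long enough
                # that measurement noise at low OD does not dominate the
                # slope, but capped at ~30% of the curve's rise duration so
                # the window never straddles too much of the sigmoid arc
                w_span = int(np.ceil(1.5 * np.log(2.0) / (mu0 * dt))) + 1
                lo = od.min() + 0.05 * np.ptp(od)
                hi = od.min() + 0.95 * np.ptp(od)
                t_lo = t[np.argmax(od >= lo)]
                cap = max(t.size // 3, w)
                if np.any(od >= hi):
                    rise_h = float(t[np.argmax(od >= hi)] - t_lo)
                    if rise_h > 0:
                        cap = min(cap, max(int(0.3 * rise_h / dt), w))
                w = max(w, min(w_span, cap))
        self.window_points_ = w
        log_od = np.log(od)
        best_slope = -np.inf
        best_start = t[0]
        best_mean_od = float(od[:w].mean())
        for i in range(t.size - w + 1):
            tw = t[i : i + w]
            yw = log_od[i : i + w]
            tc = tw - tw.mean()
            slope = float(tc @ (yw - yw.mean()) / (tc @ tc))
            if slope > best_slope:
                best_slope = slope
                best_start = tw[0]
                best_mean_od = float(od[i : i + w].mean())
        mu = 0.0 if self.flat_ else max(best_slope, 0.0)
        if self.saturation_correction and mu > 0:
            # A finite window averages the instantaneous log-slope
            # r * (1 - OD/K) over ODs above the inoculum, biasing mu low when
            # the culture saturates.  When the curve has visibly plateaued
            # (negligible terminal slope), rescale the window slope from
            # r * (1 - mean_window_OD / K) back to the initial-slope
            # definition r * (1 - OD0 / K).  A curve still in exponential
            # phase at the last timepoint is left untouched.
            tail_n = min(t.size, max(int(self.window_points), 10))
            tt, yy = t[-tail_n:], log_od[-tail_n:]
            tc = tt - tt.mean()
            tail_slope = float(tc @ (yy - yy.mean()) / (tc @ tc))
            if tail_slope < 0.2 * mu:
                k_hat = float(od.max())
                od0_hat = float(np.median(od[: min(3, od.size)]))
                if 0 < best_mean_od < 0.9 * k_hat and od0_hat < k_hat:
                    mu *= (1.0 - od0_hat / k_hat) / (1.0 - best_mean_od / k_hat)
        self.mu_ = mu
        self.window_start_ = float(best_start)
        return self


def max_specific_growth_rate(curve: GrowthCurve, window_points: int = 5) -> float:
    """Maximum specific growth rate mu (h^-1) of one background-subtracted
    OD curve; see :class:`GrowthRateEstimator`."""
    return GrowthRateEstimator(window_points=window_points).fit(curve).mu_


def normalize_to_reference(values, reference_value: float):
    """Normalize kinetic parameters against the reference strain's value for
    the same medium (plain division)."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    return np.asarray(values, dtype=float) / reference_value
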