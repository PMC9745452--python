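"""Rate-of-change decay statistics and the rapid/slow phase partition.

The headline statistic is the time at which dY/dt has decayed by 90%
from its peak ("time to 90% decay", t90): for the one-phase association
curve the derivative Ymax*k*exp(-k t) peaks at t = 0 and the closed form
is t90 = ln(10)/k.  A numeric-grid route is kept as an independent
cross-check, and an empirical estimator handles continuous LI traces.
Times before t90 belong to the rapidly-increasing phase, times at or
after it to the slowly-increasing phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import LiTrace
from .errors import (
    DegenerateFitError,
    FitInputError,
    ModelError,
    NoRiseError,
)
from .growth import MODEL_LINEAR, MODEL_ONE_PHASE, GrowthFit

__all__ = [
    "PHASE_RAPID",
    "PHASE_SLOW",
    "DecayResult",
    "PhasePartition",
    "derivative_curve",
    "time_to_90_decay",
    "time_to_90_decay_empirical",
    "phase_partition",
]

PHASE_RAPID = "rapidly_increasing"
PHASE_SLOW = "slowly_increasing"

#: Default numeric-grid step (s) and the decay fraction defining t90.
DEFAULT_GRID_STEP = 0.05
DECAY_FRACTION = 0.10


@dataclass(frozen=True)
class DecayResult:
    """Peak dY/dt, its time, and the time of 90% decay from that peak.

    ``t90`` is None (``crossed`` False) when an empirical trace ends
    before the derivative decays below 10% of its peak.
    """

    t_peak: float
    peak_rate: float
    t90: float | None
    method: str
    crossed: bool = True


@dataclass(frozen=True)
class PhasePartition:
    """Phase labels for queried times relative to the t90 boundary.

    A time exactly equal to the boundary is labelled slowly-increasing
    (the boundary closes on the slow side).
    """

    boundary: float
    times: tuple[float, ...]
    labels: tuple[str, ...]

    @staticmethod
    def label_for(t: float, boundary: float) -> str:
        return PHASE_RAPID if t < boundary else PHASE_SLOW


def _require_usable(fit: GrowthFit) -> None:
    if not fit.converged or fit.degenerate:
        raise DegenerateFitError(
            f"refusing decay analysis on degenerate/unconverged fit: {fit.message}"
        )


def derivative_curve(
    fit: GrowthFit,
    grid_step: float = DEFAULT_GRID_STEP,
    horizon: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample dY/dt of a fitted curve on a uniform grid over [0, horizon].

    For the one-phase model this is the analytic Ymax*k*exp(-k t);
    for a linear fit a constant series equal to the slope.  The default
    horizon is 1.5x the largest fitted time.
    """
    _require_usable(fit)
    if not (grid_step > 0):
        raise FitInputError("grid_step must be positive")
    if horizon is None:
        horizon = 1.5 * fit.t_max
    t = np.arange(0.0, horizon + grid_step / 2, grid_step)
    if fit.model == MODEL_ONE_PHASE:
        d = fit.ymax * fit.k * np.exp(-fit.k * t)
    elif fit.model == MODEL_LINEAR:
        d = np.full_like(t, fit.k)
    else:  # pragma: no cover - enum guard
        raise ModelError(f"unknown model {fit.model!r}")
    return t, d


def time_to_90_decay(
    fit: GrowthFit,
    method: str = "closed_form",
    grid_step: float = DEFAULT_GRID_STEP,
) -> DecayResult:
    """Time for dY/dt of a saturating fit to fall to 10% of its peak.

    ``closed_form`` returns t90 = ln(10)/k with t_peak = 0 and
    peak_rate = Ymax*k.  ``numeric_grid`` samples the derivative on a
    uniform grid (step ``grid_step``, horizon 1.5x the last fitted time,
    doubled until the crossing is bracketed) and reports the first node
    at or below the 10% threshold; ties at exactly 10% count as crossed.

    Raises
    ------
    ModelError
        For a linear fit: decay time undefined for a non-saturating model.
    DegenerateFitError
        For degenerate or unconverged fits.
    """
    if fit.model == MODEL_LINEAR:
        raise ModelError("decay time undefined for non-saturating model")
    _require_usable(fit)
    peak_rate = fit.ymax * fit.k
    if method == "closed_form":
        return DecayResult(
            t_peak=0.0, peak_rate=peak_rate,
            t90=math.log(10.0) / fit.k, method="closed_form",
        )
    if method != "numeric_grid":
        raise ValueError(f"unknown method {method!r}; use closed_form or numeric_grid")
    horizon = max(1.5 * fit.t_max, 10 * grid_step)
    threshold = DECAY_FRACTION * peak_rate * (1 + 1e-12)
    for _ in range(64):
        t, d = derivative_curve(fit, grid_step=grid_step, horizon=horizon)
        i_peak = int(np.argmax(d))
        below = np.flatnonzero(d[i_peak:] <= threshold)
        if below.size:
            return DecayResult(
                t_peak=float(t[i_peak]), peak_rate=float(d[i_peak]),
                t90=float(t[i_peak + below[0]]), method="numeric_grid",
            )
        horizon *= 2.0
    raise RuntimeError("derivative never decayed below threshold")  # pragma: no cover


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with odd-reflection (antisymmetric) padding.

    Odd reflection about the end values preserves the local slope at the
    boundaries, which keeps the derivative estimate unbiased at the trace
    start where the peak rate occurs.
    """
    if window <= 1:
        return y.astype(float)
    pad = window // 2
    left = 2 * y[0] - y[pad:0:-1]
    right = 2 * y[-1] - y[-2 : -pad - 2 : -1]
    padded = np.concatenate([left, y, right])
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def time_to_90_decay_empirical(
    trace: LiTrace,
    smoothing_window: float = 1.0,
    from_peak: bool = False,
) -> DecayResult:
    """t90 estimated directly from a sampled trace.

    The trace is smoothed with a centered moving average of width
    ``smoothing_window`` seconds, differentiated by centered finite
    differences, and the first time after the derivative peak at which
    the derivative is at or below 10% of the peak is located by linear
    interpolation between samples.  By default times are reported from
    the trace start; ``from_peak=True`` subtracts the peak time.

    The crossing is reported absent (``crossed=False``, ``t90=None``)
    when the derivative never decays below threshold within the trace.

    Raises
    ------
    FitInputError
        Trace shorter than 5 s or fewer than 20 samples.
    NoRiseError
        No positive derivative anywhere ("no rise detected").
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.li_values, dtype=float)
    if t.size < 20 or (t[-1] - t[0]) < 5.0:
        raise FitInputError("trace must span >= 5 s with >= 20 samples")
    dt = float(np.median(np.diff(t)))
    window = max(1, int(round(smoothing_window / dt)))
    if window % 2 == 0:
        window += 1
    window = min(window, 2 * (t.size // 2) - 1)
    y_s = _moving_average(y, window)
    d = np.gradient(y_s, t)
    i_peak = int(np.argmax(d))
    peak_rate = float(d[i_peak])
    if peak_rate <= 0:
        raise NoRiseError("no rise detected (peak dY/dt <= 0)")
    threshold = DECAY_FRACTION * peak_rate * (1 + 1e-12)
    tail = d[i_peak:]
    below = np.flatnonzero(tail <= threshold)
    if below.size == 0:
        return DecayResult(
            t_peak=float(t[i_peak]), peak_rate=peak_rate, t90=None,
            method="empirical", crossed=False,
        )
    j = i_peak + int(below[0])
    if j == i_peak:
        t_cross = float(t[j])
    else:
        # linear interpolation between the bracketing samples
        d0, d1 = d[j - 1], d[j]
        frac = (d0 - threshold) / (d0 - d1) if d0 != d1 else 1.0
        t_cross = float(t[j - 1] + frac * (t[j] - t[j - 1]))
    if from_peak:
        t_cross -= float(t[i_peak])
    return DecayResult(
        t_peak=float(t[i_peak]), peak_rate=peak_rate, t90=t_cross,
        method="empirical", crossed=True,
    )


def phase_partition(fit: GrowthFit, times) -> PhasePartition:
    """Label queried times as rapidly/slowly increasing around t90."""
    result = time_to_90_decay(fit, method="closed_form")
    return partition_at_boundary(result.t90, times)


def partition_at_boundary(boundary: float, times) -> PhasePartition:
    """Phase partition against an explicit t90 boundary (s)."""
    times = tuple(float(x) for x in np.atleast_1d(np.asarray(times, dtype=float)))
    labels = tuple(PhasePartition.label_for(x, boundary) for x in times)
    return PhasePartition(boundary=float(boundary), times=times, labels=labels)
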