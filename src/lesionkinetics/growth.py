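"""Saturating and linear growth-curve fitting, prediction, and inversion.

Responses (LI drop, lesion depth, lesion diameter) rise with RF delivery
time toward a plateau and are modelled with the one-phase association
curve Y(t) = Ymax * (1 - exp(-k t)) through the origin; lesion volume is
fitted linearly.  Each duration is a different lesion, so fits pool all
replicates at all durations as independent points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateFitError,
    FitInputError,
    ModelError,
    UnreachableThresholdError,
)

__all__ = [
    "MODEL_ONE_PHASE",
    "MODEL_LINEAR",
    "K_BOUNDS",
    "GrowthFit",
    "fit_one_phase",
    "fit_linear",
    "predict",
    "time_to_threshold",
]

MODEL_ONE_PHASE = "one_phase_association"
MODEL_LINEAR = "linear"

#: Rate-constant search box (1/s) for the saturating model.
K_BOUNDS = (1e-6, 10.0)

#: Relative proximity to a bound that flags a fit as degenerate.
_BOUND_MARGIN = 0.01


@dataclass(frozen=True)
class GrowthFit:
    """A fitted growth curve for one setting and one response.

    For ``one_phase_association`` the parameters are the plateau ``ymax``
    and rate constant ``k`` (1/s); for ``linear`` the slope is stored in
    ``k`` with ``ymax`` None and an explicit ``intercept``.
    ``degenerate`` marks fits whose rate or plateau estimate sits against
    a search bound; downstream decay statistics refuse such fits.
    """

    model: str
    k: float
    ymax: float | None
    intercept: float
    r_squared: float
    n_points: int
    converged: bool
    degenerate: bool
    message: str
    t_max: float
    response_label: str | None = None

    def to_dict(self) -> dict:
        """JSON-serialisable export of the fit."""
        return asdict(self)


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return float(min(1.0, max(0.0, 1.0 - ss_res / ss_tot)))


def _as_xy(times, values) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise FitInputError("times and values must be 1-D and of equal length")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
        raise FitInputError("times and values must be finite")
    if np.any(t < 0):
        raise FitInputError("times must be non-negative")
    return t, y


def fit_one_phase(
    times: Sequence[float],
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    response_label: str | None = None,
) -> GrowthFit:
    """Least-squares fit of Y(t) = Ymax*(1 - exp(-k t)) with Y(0) = 0.

    Requires at least 3 distinct time points and non-negative values.
    Initialisation: Ymax0 = 1.05 * max(y); k0 from an origin-constrained
    regression of -log(1 - y/Ymax0) on t over points with y < 0.95*Ymax0.
    Bounded trust-region least squares with k in ``K_BOUNDS`` and
    Ymax in (0, 10*max(y)].  A rate or plateau estimate within 1% of a
    bound flags the fit degenerate (e.g. effectively linear data push
    the plateau to its cap).

    Raises
    ------
    FitInputError
        Fewer than 3 distinct times, or negative values.
    """
    t, y = _as_xy(times, values)
    if np.unique(t).size < 3:
        raise FitInputError("at least 3 distinct time points are required")
    if np.any(y < 0):
        raise FitInputError("values must be non-negative")
    w = None
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if w.shape != y.shape or np.any(w < 0):
            raise FitInputError("weights must be non-negative and match values")

    y_max = float(y.max())
    n = int(t.size)
    t_max = float(t.max())
    if y_max <= 0.0:
        return GrowthFit(
            model=MODEL_ONE_PHASE, k=float("nan"), ymax=0.0, intercept=0.0,
            r_squared=0.0, n_points=n, converged=False, degenerate=True,
            message="all values are zero; no rise to fit", t_max=t_max,
            response_label=response_label,
        )

    ymax0 = 1.05 * y_max
    ymax_hi = 10.0 * y_max
    mask = (y > 0) & (y < 0.95 * ymax0) & (t > 0)
    if mask.any():
        z = -np.log1p(-y[mask] / ymax0)
        denom = float(np.sum(t[mask] ** 2))
        k0 = float(np.sum(t[mask] * z) / denom) if denom > 0 else 0.05
    else:
        k0 = 0.05
    k0 = float(np.clip(k0, 10 * K_BOUNDS[0], 0.5 * K_BOUNDS[1]))

    def residuals(p):
        ymax, k = p
        r = ymax * -np.expm1(-k * t) - y
        return r if w is None else w * r

    result = optimize.least_squares(
        residuals,
        x0=[ymax0, k0],
        bounds=([1e-12, K_BOUNDS[0]], [ymax_hi, K_BOUNDS[1]]),
        method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    ymax_hat, k_hat = (float(v) for v in result.x)
    y_hat = ymax_hat * -np.expm1(-k_hat * t)
    r2 = _r_squared(y, y_hat)

    degenerate = False
    message = "ok"
    if k_hat <= K_BOUNDS[0] * (1 + _BOUND_MARGIN):
        degenerate = True
        message = f"rate constant at lower bound ({k_hat:.3g}/s): no curvature resolved"
    elif k_hat >= K_BOUNDS[1] * (1 - _BOUND_MARGIN):
        degenerate = True
        message = f"rate constant at upper bound ({k_hat:.3g}/s): rise faster than resolvable"
    elif ymax_hat >= ymax_hi * (1 - _BOUND_MARGIN):
        degenerate = True
        message = (
            f"plateau at search cap ({ymax_hat:.3g}): no saturation in the data "
            "(response may be effectively linear)"
        )
    if not result.success:
        message = f"optimizer did not converge: {result.message}"

    return GrowthFit(
        model=MODEL_ONE_PHASE, k=k_hat, ymax=ymax_hat, intercept=0.0,
        r_squared=r2, n_points=n, converged=bool(result.success),
        degenerate=degenerate, message=message, t_max=t_max,
        response_label=response_label,
    )


def fit_linear(
    times: Sequence[float],
    values: Sequence[float],
    response_label: str | None = None,
) -> GrowthFit:
    """Ordinary least-squares line; the slope is stored in ``k``."""
    t, y = _as_xy(times, values)
    if np.unique(t).size < 2:
        raise FitInputError("at least 2 distinct time points are required")
    res = stats.linregress(t, y)
    slope = float(res.slope)
    intercept = float(res.intercept)
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue**2)
    return GrowthFit(
        model=MODEL_LINEAR, k=slope, ymax=None, intercept=intercept,
        r_squared=r2, n_points=int(t.size), converged=True, degenerate=False,
        message="ok", t_max=float(t.max()), response_label=response_label,
    )


def predict(fit: GrowthFit, t) -> float | np.ndarray:
    """Model mean response at time(s) ``t`` (requires a converged fit)."""
    if not fit.converged:
        raise DegenerateFitError(f"cannot predict from unconverged fit: {fit.message}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise FitInputError("prediction times must be >= 0")
    if fit.model == MODEL_ONE_PHASE:
        out = fit.ymax * -np.expm1(-fit.k * t_arr)
    elif fit.model == MODEL_LINEAR:
        out = fit.intercept + fit.k * t_arr
    else:  # pragma: no cover - enum guard
        raise ModelError(f"unknown model {fit.model!r}")
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def time_to_threshold(fit: GrowthFit, y_star: float) -> float:
    """Invert the fitted curve: time at which the mean reaches ``y_star``.

    One-phase: t = -log(1 - y_star/Ymax) / k; raises
    :class:`UnreachableThresholdError` (carrying the plateau) when
    ``y_star >= Ymax``.  Linear: t = (y_star - intercept) / slope.
    """
    if not (y_star > 0):
        raise FitInputError("threshold must be positive")
    if not fit.converged or fit.degenerate:
        raise DegenerateFitError(
            f"refusing threshold inversion on degenerate/unconverged fit: {fit.message}"
        )
    if fit.model == MODEL_ONE_PHASE:
        if y_star >= fit.ymax:
            raise UnreachableThresholdError(
                f"threshold {y_star:g} is at or above the fitted plateau "
                f"{fit.ymax:g}; the curve never reaches it",
                ymax=fit.ymax,
            )
        return float(-math.log1p(-y_star / fit.ymax) / fit.k)
    if fit.model == MODEL_LINEAR:
        if fit.k <= 0:
            raise UnreachableThresholdError(
                f"non-positive slope {fit.k:g}: threshold never reached", ymax=None
            )
        return float((y_star - fit.intercept) / fit.k)
    raise ModelError(f"unknown model {fit.model!r}")  # pragma: no cover
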