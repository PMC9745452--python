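"""Correlation, dose-trend, and group-comparison statistics.

The trend test is the Cochran–Armitage statistic for proportions across
ordered groups, with delivery times as the default dose scores and an
optional exact/permutation p-value for small tables.  Power-group
comparisons use the unequal-variance (Welch) two-sample test per
matched time/contact-force cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import AblationRecord, lesion_volume
from .errors import FitInputError, ZeroVarianceError

__all__ = [
    "CorrelationResult",
    "TrendTestResult",
    "CellComparison",
    "pearson_correlation",
    "cochran_armitage_trend",
    "compare_power_groups",
    "RESPONSE_GETTERS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TrendTestResult:
    """Signed trend statistic with asymptotic and (optional) exact p.

    ``z_statistic`` is a standard-normal deviate whose sign flips when
    the group order is reversed; ``p_value`` is the two-sided normal
    probability (one-sided available via the test's ``alternative``).
    """

    z_statistic: float
    p_value: float
    scores: tuple[float, ...]
    p_exact: float | None = None
    exact_method: str | None = None


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a t-distributed two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitInputError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise FitInputError("at least 3 paired observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


def _trend_z(
    successes: np.ndarray, totals: np.ndarray, scores: np.ndarray
) -> float:
    n_total = totals.sum()
    p_bar = successes.sum() / n_total
    numerator = float(np.sum(scores * (successes - totals * p_bar)))
    variance = p_bar * (1 - p_bar) * (
        float(np.sum(totals * scores**2))
        - float(np.sum(totals * scores)) ** 2 / n_total
    )
    return numerator / math.sqrt(variance)


def cochran_armitage_trend(
    successes: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
    alternative: str = "two-sided",
    exact: str | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> TrendTestResult:
    """Cochran–Armitage test for a monotone trend in proportions.

    Z = sum_i s_i (x_i - n_i p) / sqrt( p(1-p) [sum n_i s_i^2 -
    (sum n_i s_i)^2 / N] ) with p the pooled proportion.  ``scores``
    default to group indices 1..g; in the pipeline the actual delivery
    times are passed as the dose metric.  Set ``exact`` to
    ``"enumerate"`` for the exact conditional (fixed-margin) p-value, or
    ``"permutation"`` for a seeded Monte-Carlo approximation with
    ``n_permutations`` draws.

    Raises
    ------
    ZeroVarianceError
        All-success or all-failure pooled table.
    """
    x = np.asarray(successes, dtype=np.int64)
    n = np.asarray(totals, dtype=np.int64)
    if x.shape != n.shape or x.ndim != 1 or x.size < 2:
        raise FitInputError("need >= 2 groups with matching successes/totals")
    if np.any(x < 0) or np.any(x > n) or np.any(n <= 0):
        raise FitInputError("require 0 <= successes <= totals with positive totals")
    if scores is None:
        s = np.arange(1.0, x.size + 1.0)
    else:
        s = np.asarray(scores, dtype=float)
        if s.shape != x.shape or np.any(np.diff(s) <= 0):
            raise FitInputError("scores must be strictly increasing, one per group")
    total_succ = int(x.sum())
    n_total = int(n.sum())
    if total_succ == 0 or total_succ == n_total:
        raise ZeroVarianceError(
            "pooled table is all-failure or all-success: trend undefined"
        )
    z = _trend_z(x, n, s)
    if alternative == "two-sided":
        p = math.erfc(abs(z) / math.sqrt(2.0))
    elif alternative == "greater":
        p = 0.5 * math.erfc(z / math.sqrt(2.0))
    elif alternative == "less":
        p = 0.5 * math.erfc(-z / math.sqrt(2.0))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    p_exact = None
    exact_method = None
    if exact == "enumerate":
        p_exact = _exact_trend_p(x, n, s, z, alternative)
        exact_method = "enumerate"
    elif exact == "permutation":
        p_exact = _permutation_trend_p(x, n, s, z, alternative, n_permutations, seed)
        exact_method = "permutation"
    elif exact is not None:
        raise ValueError(f"unknown exact mode {exact!r}")
    return TrendTestResult(
        z_statistic=float(z), p_value=float(p), scores=tuple(s),
        p_exact=p_exact, exact_method=exact_method,
    )


def _more_extreme(z_ref: float, z: float, alternative: str) -> bool:
    eps = 1e-12
    if alternative == "two-sided":
        return abs(z) >= abs(z_ref) - eps
    if alternative == "greater":
        return z >= z_ref - eps
    return z <= z_ref + eps


def _exact_trend_p(
    x: np.ndarray, n: np.ndarray, s: np.ndarray, z_obs: float, alternative: str
) -> float:
    """Exact conditional p: enumerate all tables with the observed margins.

    Allocation probabilities follow the multivariate hypergeometric law
    given the pooled success count; feasible only for small tables.
    """
    total_succ = int(x.sum())
    n_total = int(n.sum())
    denom = math.comb(n_total, total_succ)
    groups = len(n)
    p = 0.0

    def rec(idx: int, remaining: int, alloc: list[int], weight: int):
        nonlocal p
        if idx == groups - 1:
            if remaining > n[idx]:
                return
            alloc.append(remaining)
            w = weight * math.comb(int(n[idx]), remaining)
            z = _trend_z(np.array(alloc), n, s)
            if _more_extreme(z_obs, z, alternative):
                p += w / denom
            alloc.pop()
            return
        lo = max(0, remaining - int(n[idx + 1 :].sum()))
        hi = min(int(n[idx]), remaining)
        for xi in range(lo, hi + 1):
            alloc.append(xi)
            rec(idx + 1, remaining - xi, alloc, weight * math.comb(int(n[idx]), xi))
            alloc.pop()

    rec(0, total_succ, [], 1)
    return min(1.0, p)


def _permutation_trend_p(
    x: np.ndarray, n: np.ndarray, s: np.ndarray, z_obs: float,
    alternative: str, n_permutations: int, seed: int | None,
) -> float:
    rng = np.random.default_rng(seed)
    n_total = int(n.sum())
    pooled = np.zeros(n_total, dtype=np.int64)
    pooled[: int(x.sum())] = 1
    edges = np.cumsum(n)[:-1]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        x_perm = np.array([g.sum() for g in np.split(perm, edges)])
        if _more_extreme(z_obs, _trend_z(x_perm, n, s), alternative):
            count += 1
    return count / n_permutations


RESPONSE_GETTERS = {
    "li_drop": lambda r: r.li_drop_ohm,
    "depth": lambda r: r.geometry.a,
    "diameter": lambda r: r.geometry.b,
    "volume": lambda r: lesion_volume(r.geometry),
}


@dataclass(frozen=True)
class CellComparison:
    """Welch comparison of the two power groups in one (CF, time) cell."""

    cf_g: float
    time_s: float
    power_low_w: float
    power_high_w: float
    n_low: int
    n_high: int
    statistic: float
    p_value: float
    significant: bool


def compare_power_groups(
    records: Sequence[AblationRecord],
    response: str,
    at_time: float | None = None,
    alpha: float = 0.05,
) -> tuple[list[CellComparison], list[tuple[float, float, str]]]:
    """Per-cell unequal-variance comparison between the two power groups.

    For every (contact force, time) cell present for both powers with at
    least 2 replicates each, runs a two-sided Welch test on ``response``
    and marks significance at ``alpha`` (no multiplicity correction —
    mirrors per-point marking on dose-response plots).  Cells that
    cannot be tested are skipped and returned in the second element as
    (cf, time, reason), also logged.
    """
    if response not in RESPONSE_GETTERS:
        raise ValueError(
            f"unknown response {response!r}; expected one of {sorted(RESPONSE_GETTERS)}"
        )
    getter = RESPONSE_GETTERS[response]
    powers = sorted({r.setting.power_w for r in records})
    if len(powers) != 2:
        raise FitInputError(
            f"power-group comparison needs exactly 2 power levels, found {powers}"
        )
    p_low, p_high = powers
    cells = sorted(
        {(r.setting.cf_g, r.duration_s) for r in records
         if at_time is None or r.duration_s == at_time}
    )
    results: list[CellComparison] = []
    skipped: list[tuple[float, float, str]] = []
    for cf, t in cells:
        lo = [getter(r) for r in records
              if r.setting.cf_g == cf and r.duration_s == t
              and r.setting.power_w == p_low]
        hi = [getter(r) for r in records
              if r.setting.cf_g == cf and r.duration_s == t
              and r.setting.power_w == p_high]
        if len(lo) < 2 or len(hi) < 2:
            reason = (
                f"missing or underpowered cell: n({p_low:g} W)={len(lo)}, "
                f"n({p_high:g} W)={len(hi)}"
            )
            logger.warning("skipping CF %g g, t %g s: %s", cf, t, reason)
            skipped.append((cf, t, reason))
            continue
        lo_a, hi_a = np.asarray(lo), np.asarray(hi)
        if np.ptp(lo_a) == 0 and np.ptp(hi_a) == 0:
            # zero variance in both groups: defined by means alone
            stat, p = 0.0, 1.0
            if lo_a[0] != hi_a[0]:
                stat, p = math.inf if hi_a[0] > lo_a[0] else -math.inf, 0.0
        else:
            stat, p = sps.ttest_ind(hi_a, lo_a, equal_var=False)
        results.append(
            CellComparison(
                cf_g=cf, time_s=t, power_low_w=p_low, power_high_w=p_high,
                n_low=len(lo), n_high=len(hi),
                statistic=float(stat), p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    return results, skipped
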