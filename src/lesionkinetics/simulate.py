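"""Synthetic-experiment generator with the factorial design of the study.

Each (power, contact force, delivery time) cell draws ``n`` independent
endpoint records whose mean responses follow one-phase association
truth curves, with additive (or CV-scaled) Gaussian noise truncated at
zero by resampling.  Steam pops are Bernoulli draws from a per-power
logistic-in-time model.  Every cell owns its own RNG stream, derived
from the master seed and the cell coordinates, so adding cells never
perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DESIGN_FORCES_G,
    DESIGN_REPLICATES,
    DESIGN_TIMES_S,
    AblationRecord,
    AblationSetting,
    LesionGeometry,
    LiTrace,
)
from .errors import CalibrationError, ConfigError

__all__ = [
    "RESPONSES",
    "ResponseTruth",
    "PopModel",
    "ExperimentConfig",
    "truth_from_decay_time",
    "simulate_experiment",
    "simulate_li_trace",
    "pop_probability",
]

#: Responses carried by every synthetic record.
RESPONSES = ("li_drop", "depth", "diameter")

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ResponseTruth:
    """Generating parameters of one response: plateau, rate, noise scale.

    Exactly one of ``noise_sd`` (additive SD, response units) or
    ``noise_cv`` (multiplicative coefficient of variation on the mean)
    must be set; either may be zero for a noiseless truth.
    """

    ymax: float
    k: float
    noise_sd: float | None = None
    noise_cv: float | None = None

    def __post_init__(self):
        if not (self.ymax > 0):
            raise ConfigError("ymax must be positive")
        if not (self.k > 0):
            raise ConfigError("k must be positive")
        if (self.noise_sd is None) == (self.noise_cv is None):
            raise ConfigError("exactly one of noise_sd / noise_cv must be set")
        scale = self.noise_sd if self.noise_sd is not None else self.noise_cv
        if scale < 0:
            raise ConfigError("noise scale must be >= 0")

    def mean_at(self, t: float) -> float:
        return self.ymax * -math.expm1(-self.k * t)

    def sd_at(self, t: float) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return self.noise_cv * self.mean_at(t)

    @property
    def t90(self) -> float:
        """Decay time implied by the rate constant: ln(10)/k."""
        return _LN10 / self.k


@dataclass(frozen=True)
class PopModel:
    """Logistic steam-pop probability in delivery time: expit(b0 + b1*t)."""

    intercept: float
    slope: float

    def probability(self, t: float) -> float:
        if t < 0:
            raise ConfigError("time must be >= 0")
        z = self.intercept + self.slope * t
        if z >= 0:
            return 1.0 / (1.0 + math.exp(-z))
        e = math.exp(z)
        return e / (1.0 + e)


@dataclass(frozen=True)
class ExperimentConfig:
    """Factorial design, generating truths, pop models, and master seed.

    ``truths`` maps (power_w, cf_g, response) to a :class:`ResponseTruth`
    for every response in :data:`RESPONSES`.  Geometry coupling constants
    ``c_ratio``/``d_ratio`` derive the secondary lesion axes from the
    primary ones (c = c_ratio*a, d = d_ratio*b) — a synthetic-only
    convention so that lesion volume is computable.
    """

    times_by_power: Mapping[float, tuple[float, ...]]
    forces: tuple[float, ...]
    n_per_cell: int
    truths: Mapping[tuple[float, float, str], ResponseTruth]
    pop_models: Mapping[float, PopModel]
    seed: int = 0
    c_ratio: float = 0.5
    d_ratio: float = 0.8

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ConfigError("n_per_cell must be >= 1")
        if not self.times_by_power or not self.forces:
            raise ConfigError("design must declare at least one power and force")
        for power, times in self.times_by_power.items():
            if power not in self.pop_models:
                raise ConfigError(f"no pop model for power {power:g} W")
            if any(t <= 0 for t in times):
                raise ConfigError("delivery times must be positive")
            for cf in self.forces:
                for resp in RESPONSES:
                    if (power, cf, resp) not in self.truths:
                        raise ConfigError(
                            f"missing truth for ({power:g} W, {cf:g} g, {resp})"
                        )

    @property
    def is_reference_design(self) -> bool:
        """True if the design matches the declared factorial layout exactly."""
        return (
            {p: tuple(t) for p, t in self.times_by_power.items()} == DESIGN_TIMES_S
            and tuple(self.forces) == DESIGN_FORCES_G
            and self.n_per_cell == DESIGN_REPLICATES
        )

    def cells(self):
        for power in sorted(self.times_by_power):
            for cf in self.forces:
                for t in self.times_by_power[power]:
                    yield power, cf, t


def truth_from_decay_time(
    t90: float,
    anchor: tuple[float, float] | None = None,
    ymax: float = 1.0,
    noise_sd: float | None = None,
    noise_cv: float | None = None,
) -> ResponseTruth:
    """Calibrate a generating truth from a decay time (and optional anchor).

    The rate constant is the model-implied inversion k = ln(10)/t90.
    Given an anchor point (t*, y*) on the mean curve, the plateau is
    solved from y* = Ymax*(1 - exp(-k t*)); otherwise the supplied
    ``ymax`` constant is used.  If neither noise field is given the
    truth is noiseless (additive SD 0).
    """
    if not (t90 > 0):
        raise CalibrationError("t90 must be positive")
    k = _LN10 / t90
    if anchor is not None:
        t_star, y_star = anchor
        if not (t_star > 0) or not (y_star > 0):
            raise CalibrationError("anchor time and response must be positive")
        denom = -math.expm1(-k * t_star)
        ymax = y_star / denom
        if ymax <= y_star:
            raise CalibrationError(
                f"anchor inconsistent: implied plateau {ymax:g} <= anchor {y_star:g}"
            )
    if noise_sd is None and noise_cv is None:
        noise_sd = 0.0
    return ResponseTruth(ymax=ymax, k=k, noise_sd=noise_sd, noise_cv=noise_cv)


def _cell_rng(seed: int, power: float, cf: float, t: float) -> np.random.Generator:
    """Per-cell stream: seeded from (master seed, power, CF, time in ms)."""
    entropy = (
        int(seed),
        int(round(power * 10)),
        int(round(cf * 10)),
        int(round(t * 1000)),
    )
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _draw_nonneg(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Gaussian draws truncated at zero by resampling (no point mass at 0)."""
    if sd == 0.0:
        return np.full(size, mean)
    out = mean + sd * rng.standard_normal(size)
    for _ in range(1000):
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
    raise RuntimeError("resampling failed to produce non-negative draws")


def simulate_experiment(
    config: ExperimentConfig, seed: int | None = None
) -> list[AblationRecord]:
    """Draw one full factorial experiment as a list of endpoint records.

    Per cell: ``n_per_cell`` records with depth (axis a), diameter
    (axis b) and LI drop drawn from their truth curves, c and d coupled
    by the config ratios, and steam pops from the per-power logistic
    model.  Identical seed implies identical output.
    """
    master = config.seed if seed is None else seed
    records: list[AblationRecord] = []
    n = config.n_per_cell
    for power, cf, t in config.cells():
        rng = _cell_rng(master, power, cf, t)
        depth_truth = config.truths[(power, cf, "depth")]
        diam_truth = config.truths[(power, cf, "diameter")]
        li_truth = config.truths[(power, cf, "li_drop")]
        a = _draw_nonneg(rng, depth_truth.mean_at(t), depth_truth.sd_at(t), n)
        b = _draw_nonneg(rng, diam_truth.mean_at(t), diam_truth.sd_at(t), n)
        li = _draw_nonneg(rng, li_truth.mean_at(t), li_truth.sd_at(t), n)
        p_pop = config.pop_models[power].probability(t)
        pops = rng.random(n) < p_pop
        setting = AblationSetting(power_w=power, cf_g=cf)
        for rep in range(n):
            records.append(
                AblationRecord(
                    setting=setting,
                    duration_s=float(t),
                    li_drop_ohm=float(li[rep]),
                    geometry=LesionGeometry(
                        a=float(a[rep]),
                        b=float(b[rep]),
                        c=float(config.c_ratio * a[rep]),
                        d=float(config.d_ratio * b[rep]),
                    ),
                    steam_pop=bool(pops[rep]),
                    replicate=rep + 1,
                )
            )
    return records


def simulate_li_trace(
    truth: ResponseTruth,
    duration: float,
    rate: float = 10.0,
    seed: int | None = None,
) -> LiTrace:
    """Sampled LI-drop trace: one-phase mean plus seeded Gaussian noise.

    ``rate`` is the sampling frequency in Hz (>= 1); the trace has
    round(duration*rate) + 1 samples starting at t = 0.
    """
    if not (duration > 0):
        raise ConfigError("duration must be positive")
    if rate < 1:
        raise ConfigError("sampling rate must be >= 1 Hz")
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    mean = truth.ymax * -np.expm1(-truth.k * t)
    if truth.noise_sd is not None:
        sd = np.full(n, truth.noise_sd)
    else:
        sd = truth.noise_cv * mean
    rng = np.random.default_rng(seed)
    values = mean + sd * rng.standard_normal(n)
    return LiTrace(times=tuple(t.tolist()), li_values=tuple(values.tolist()))


def pop_probability(
    power: float, t: float, pop_models: Mapping[float, PopModel]
) -> float:
    """Steam-pop probability for a power at time ``t`` under the config."""
    if power not in pop_models:
        raise ConfigError(f"no pop model for power {power:g} W")
    return pop_models[power].probability(t)
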