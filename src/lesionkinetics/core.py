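"""Domain types, record validation, and lesion-volume computation.

One ablation experiment is a factorial sweep over power, contact force and
RF delivery time; each application yields an endpoint local-impedance (LI)
drop, a lesion measured along four axes, and a steam-pop flag.  This module
defines those records, their invariants, and the half-ellipsoid-style
volume estimate derived from the four axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np

from .errors import EmptyDatasetError, ValidationError

__all__ = [
    "DESIGN_POWERS_W",
    "DESIGN_FORCES_G",
    "DESIGN_TIMES_S",
    "DESIGN_REPLICATES",
    "AblationSetting",
    "LesionGeometry",
    "AblationRecord",
    "LiTrace",
    "ValidationIssue",
    "lesion_volume",
    "validate_records",
]

#: Factorial design of the default experiment.
DESIGN_POWERS_W: tuple[float, ...] = (40.0, 50.0)
DESIGN_FORCES_G: tuple[float, ...] = (10.0, 30.0, 50.0)
DESIGN_TIMES_S: dict[float, tuple[float, ...]] = {
    40.0: (10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    50.0: (5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
}
DESIGN_REPLICATES: int = 10


@dataclass(frozen=True)
class AblationSetting:
    """A power / contact-force combination.

    Any positive pair is accepted at construction; membership in the
    declared design sets is enforced only by :func:`validate_records`
    with ``strict_design=True``.
    """

    power_w: float
    cf_g: float

    def __post_init__(self):
        if not (self.power_w > 0):
            raise ValidationError("power_w must be positive", field="power_w")
        if not (self.cf_g > 0):
            raise ValidationError("cf_g must be positive", field="cf_g")

    @property
    def in_design(self) -> bool:
        """True if the setting belongs to the declared factorial design."""
        return self.power_w in DESIGN_POWERS_W and self.cf_g in DESIGN_FORCES_G


@dataclass(frozen=True)
class LesionGeometry:
    """Four measured lesion axes (mm).

    a: maximum depth; b: maximum diameter; c: depth at the maximum
    diameter; d: surface maximum diameter.  All are non-negative and
    c cannot exceed a.  d may exceed b (shallow, surface-dominated
    lesions), so no constraint relates d and b.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"lesion axis {name!r} must be finite and >= 0, got {value}",
                    field=name,
                )
        if self.c > self.a:
            raise ValidationError(
                "depth-at-max-diameter exceeds max depth (c > a)", field="c"
            )


def lesion_volume(geometry: LesionGeometry) -> float:
    """Lesion volume (mm^3) from the four measured axes.

    volume = (pi/6) * (a*b^2 + (c*d^2)/2): the sum of a half-ellipsoid
    term for the subsurface body and a half-weighted term for the
    surface cap.  Zero iff both a*b^2 and c*d^2 vanish.
    """
    g = geometry
    return (math.pi / 6.0) * (g.a * g.b**2 + g.c * g.d**2 / 2.0)


@dataclass(frozen=True, eq=True)
class AblationRecord:
    """One RF application: setting, duration, endpoint responses, pop flag."""

    setting: AblationSetting
    duration_s: float
    li_drop_ohm: float
    geometry: LesionGeometry
    steam_pop: bool
    replicate: int
    extras: tuple = ()  # passthrough of unknown CSV columns: ((name, raw value), ...)

    def __post_init__(self):
        if not (self.duration_s > 0) or not math.isfinite(self.duration_s):
            raise ValidationError("duration_s must be positive", field="duration_s")
        if not (self.li_drop_ohm >= 0) or not math.isfinite(self.li_drop_ohm):
            raise ValidationError("li_drop_ohm must be >= 0", field="li_drop_ohm")
        if not isinstance(self.replicate, int) or isinstance(self.replicate, bool) or self.replicate < 1:
            raise ValidationError(
                "replicate must be a positive integer", field="replicate"
            )

    @property
    def volume_mm3(self) -> float:
        return lesion_volume(self.geometry)

    @classmethod
    def from_row(cls, row: Mapping[str, object]) -> "AblationRecord":
        """Build a record from a parsed CSV row mapping (raw strings allowed).

        Required keys follow the records CSV schema: power_w, cf_g, time_s,
        li_drop_ohm, depth_a_mm, diam_b_mm, depth_c_mm, surf_d_mm,
        steam_pop (0/1), replicate.  Unknown keys are preserved in
        ``extras``.
        """
        def _num(key: str) -> float:
            raw = row[key]
            try:
                return float(raw)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ValidationError(
                    f"column {key!r}: cannot parse {raw!r} as a number", field=key
                ) from None

        pop_raw = str(row["steam_pop"]).strip()
        if pop_raw not in ("0", "1"):
            raise ValidationError(
                f"column 'steam_pop': expected 0 or 1, got {row['steam_pop']!r}",
                field="steam_pop",
            )
        rep_raw = str(row["replicate"]).strip()
        try:
            replicate = int(rep_raw)
        except ValueError:
            raise ValidationError(
                f"column 'replicate': expected an integer, got {row['replicate']!r}",
                field="replicate",
            ) from None
        known = {
            "power_w", "cf_g", "time_s", "li_drop_ohm", "depth_a_mm",
            "diam_b_mm", "depth_c_mm", "surf_d_mm", "steam_pop", "replicate",
        }
        extras = tuple((k, row[k]) for k in row if k not in known)
        return cls(
            setting=AblationSetting(power_w=_num("power_w"), cf_g=_num("cf_g")),
            duration_s=_num("time_s"),
            li_drop_ohm=_num("li_drop_ohm"),
            geometry=LesionGeometry(
                a=_num("depth_a_mm"),
                b=_num("diam_b_mm"),
                c=_num("depth_c_mm"),
                d=_num("surf_d_mm"),
            ),
            steam_pop=pop_raw == "1",
            replicate=replicate,
            extras=extras,
        )


@dataclass(frozen=True)
class LiTrace:
    """A continuous LI-drop trace: strictly increasing times, one value each.

    Values are the impedance drop from baseline (Ohm), which rises
    monotonically in expectation during RF delivery.
    """

    times: tuple[float, ...]
    li_values: tuple[float, ...]

    def __post_init__(self):
        if len(self.times) != len(self.li_values):
            raise ValidationError(
                "times and li_values must have equal length", field="li_values"
            )
        t = np.asarray(self.times, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing", field="times")

    @property
    def duration_s(self) -> float:
        return self.times[-1] - self.times[0] if self.times else 0.0


@dataclass(frozen=True)
class ValidationIssue:
    """One rejected row: its position, offending field (if known), reason."""

    index: int
    reason: str
    field: str | None = None


RecordLike = Union[AblationRecord, Mapping[str, object]]


def validate_records(
    records: Iterable[RecordLike],
    strict_design: bool = False,
) -> tuple[list[AblationRecord], list[ValidationIssue]]:
    """Validate records, returning the accepted list and an issue report.

    Accepts constructed :class:`AblationRecord` objects or raw row
    mappings (coerced via :meth:`AblationRecord.from_row`).  Checks, in
    order: per-record invariants, replicate uniqueness within
    (setting, duration), and — when ``strict_design`` is on — membership
    of the power/contact-force pair in the declared design sets.

    Raises
    ------
    EmptyDatasetError
        If ``records`` is empty.
    """
    records = list(records)
    if not records:
        raise EmptyDatasetError("no records supplied")
    accepted: list[AblationRecord] = []
    issues: list[ValidationIssue] = []
    seen: set[tuple[float, float, float, int]] = set()
    for i, rec in enumerate(records):
        if not isinstance(rec, AblationRecord):
            try:
                rec = AblationRecord.from_row(rec)
            except (ValidationError, KeyError) as exc:
                if isinstance(exc, KeyError):
                    issues.append(
                        ValidationIssue(i, f"missing field {exc.args[0]!r}")
                    )
                else:
                    issues.append(ValidationIssue(i, str(exc), field=exc.field))
                continue
        key = (rec.setting.power_w, rec.setting.cf_g, rec.duration_s, rec.replicate)
        if key in seen:
            issues.append(
                ValidationIssue(
                    i,
                    f"duplicate replicate {rec.replicate} within setting "
                    f"{rec.setting.power_w:g} W / {rec.setting.cf_g:g} g at "
                    f"{rec.duration_s:g} s",
                    field="replicate",
                )
            )
            continue
        if strict_design and not rec.setting.in_design:
            issues.append(
                ValidationIssue(
                    i,
                    f"setting {rec.setting.power_w:g} W / {rec.setting.cf_g:g} g "
                    "outside the declared design (strict_design on)",
                    field="power_w" if rec.setting.power_w not in DESIGN_POWERS_W else "cf_g",
                )
            )
            continue
        seen.add(key)
        accepted.append(rec)
    return accepted, issues
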