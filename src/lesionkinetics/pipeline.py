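"""End-to-end orchestration: records I/O, full analysis, report rendering.

``run_full_analysis`` turns a validated record set into the summary
tables: per-setting decay times for each saturating response, 4-mm
depth-crossing times, LI-drop/lesion correlations, steam-pop trend
tests, and fit diagnostics.  Every table cell is produced by a module
operation — nothing is computed only inside the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import decay, growth, inference
from .core import AblationRecord, ValidationIssue, lesion_volume, validate_records
from .errors import (
    DegenerateFitError,
    EmptyDatasetError,
    FitInputError,
    ModelError,
    SchemaError,
    UnreachableThresholdError,
    ZeroVarianceError,
)

__all__ = [
    "RECORD_COLUMNS",
    "TRACE_COLUMNS",
    "SummaryReport",
    "read_records",
    "write_records",
    "run_full_analysis",
    "render_report",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "power_w", "cf_g", "time_s", "li_drop_ohm", "depth_a_mm",
    "diam_b_mm", "depth_c_mm", "surf_d_mm", "steam_pop", "replicate",
]
TRACE_COLUMNS = ["power_w", "cf_g", "replicate", "t_s", "li_ohm"]

#: Saturating responses analysed with the one-phase model.
_SATURATING = ("li_drop", "depth", "diameter")

REPORT_TABLES = (
    "decay_table", "threshold_table", "correlation_table",
    "trend_table", "fit_diagnostics",
)


@dataclass
class SummaryReport:
    """All summary tables of one analysis run, plus the fits behind them."""

    decay_table: pd.DataFrame
    threshold_table: pd.DataFrame
    correlation_table: pd.DataFrame
    trend_table: pd.DataFrame
    fit_diagnostics: pd.DataFrame
    fits: dict = field(default_factory=dict)
    records: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def read_records(path: str | Path) -> tuple[list[AblationRecord], list[ValidationIssue]]:
    """Parse a records CSV; malformed rows become issues, never silent drops.

    Unknown columns are preserved on each record (tolerant reader) with
    a warning.  A missing required column raises :class:`SchemaError`
    naming the column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}", column=col)
    extra = [c for c in df.columns if c not in RECORD_COLUMNS]
    if extra:
        logger.warning("unknown columns preserved as extras: %s", extra)
    rows = df.to_dict(orient="records")
    if not rows:
        raise EmptyDatasetError(f"no data rows in {path}")
    return validate_records(rows)


def write_records(records: Sequence[AblationRecord], path: str | Path) -> None:
    """Write records in the standard CSV schema (extras appended at the end)."""
    extra_cols: list[str] = []
    for rec in records:
        for name, _ in rec.extras:
            if name not in extra_cols:
                extra_cols.append(name)
    rows = []
    for rec in records:
        row = {
            "power_w": rec.setting.power_w,
            "cf_g": rec.setting.cf_g,
            "time_s": rec.duration_s,
            "li_drop_ohm": rec.li_drop_ohm,
            "depth_a_mm": rec.geometry.a,
            "diam_b_mm": rec.geometry.b,
            "depth_c_mm": rec.geometry.c,
            "surf_d_mm": rec.geometry.d,
            "steam_pop": int(rec.steam_pop),
            "replicate": rec.replicate,
        }
        row.update({k: v for k, v in rec.extras})
        rows.append(row)
    pd.DataFrame(rows, columns=RECORD_COLUMNS + extra_cols).to_csv(path, index=False)


def _fit_all(records, warnings):
    """One growth fit per (setting, response): saturating + linear volume."""
    fits = {}
    settings = sorted({(r.setting.power_w, r.setting.cf_g) for r in records})
    for power, cf in settings:
        subset = [r for r in records
                  if r.setting.power_w == power and r.setting.cf_g == cf]
        times = [r.duration_s for r in subset]
        for resp in _SATURATING:
            values = [inference.RESPONSE_GETTERS[resp](r) for r in subset]
            try:
                fits[(power, cf, resp)] = growth.fit_one_phase(
                    times, values, response_label=resp
                )
            except FitInputError as exc:
                warnings.append(
                    f"fit skipped for {power:g} W/{cf:g} g {resp}: {exc}"
                )
        volumes = [lesion_volume(r.geometry) for r in subset]
        try:
            fits[(power, cf, "volume")] = growth.fit_linear(
                times, volumes, response_label="volume"
            )
        except FitInputError as exc:
            warnings.append(f"fit skipped for {power:g} W/{cf:g} g volume: {exc}")
    return fits, settings


def run_full_analysis(
    records: Sequence[AblationRecord],
    threshold_depth: float = 4.0,
    strict_design: bool = False,
    include_pops: bool = True,
) -> SummaryReport:
    """Run the whole analysis on a record set and assemble the report.

    ``include_pops=False`` excludes steam-pop lesions from the growth /
    correlation analyses (they stay in the trend table, which is about
    pop incidence itself).  Deterministic given the records.
    """
    valid, issues = validate_records(records, strict_design=strict_design)
    if not valid:
        raise EmptyDatasetError(
            "no valid records after validation; issues: "
            + "; ".join(i.reason for i in issues[:10])
        )
    warnings = [f"row {i.index}: {i.reason}" for i in issues]
    analysis_records = valid if include_pops else [r for r in valid if not r.steam_pop]
    if not analysis_records:
        raise EmptyDatasetError("no records left after excluding steam pops")

    fits, settings = _fit_all(analysis_records, warnings)

    decay_rows, threshold_rows, corr_rows, trend_rows, diag_rows = [], [], [], [], []
    for power, cf in settings:
        subset = [r for r in analysis_records
                  if r.setting.power_w == power and r.setting.cf_g == cf]
        for resp in _SATURATING + ("volume",):
            fit = fits.get((power, cf, resp))
            if fit is None:
                continue
            diag_rows.append({
                "power_w": power, "cf_g": cf, "response": resp,
                "model": fit.model, "r_squared": fit.r_squared,
                "n_points": fit.n_points, "converged": fit.converged,
                "degenerate": fit.degenerate, "message": fit.message,
            })
            if resp in _SATURATING:
                try:
                    res = decay.time_to_90_decay(fit, method="closed_form")
                    decay_rows.append({
                        "power_w": power, "cf_g": cf, "response": resp,
                        "t90_s": res.t90, "method": res.method,
                    })
                except (DegenerateFitError, ModelError) as exc:
                    warnings.append(
                        f"decay skipped for {power:g} W/{cf:g} g {resp}: {exc}"
                    )
        depth_fit = fits.get((power, cf, "depth"))
        if depth_fit is not None:
            try:
                t_star = growth.time_to_threshold(depth_fit, threshold_depth)
                threshold_rows.append({
                    "power_w": power, "cf_g": cf,
                    "threshold_mm": threshold_depth,
                    "time_s": t_star, "status": "ok",
                })
            except UnreachableThresholdError as exc:
                threshold_rows.append({
                    "power_w": power, "cf_g": cf,
                    "threshold_mm": threshold_depth,
                    "time_s": np.nan, "status": "unreachable",
                })
                warnings.append(
                    f"threshold unreachable for {power:g} W/{cf:g} g: {exc}"
                )
            except DegenerateFitError as exc:
                warnings.append(
                    f"threshold skipped for {power:g} W/{cf:g} g: {exc}"
                )
        li = [r.li_drop_ohm for r in subset]
        for other in ("depth", "diameter", "volume"):
            values = [inference.RESPONSE_GETTERS[other](r) for r in subset]
            try:
                c = inference.pearson_correlation(li, values)
                corr_rows.append({
                    "power_w": power, "cf_g": cf,
                    "response": other, "r": c.r, "p_value": c.p_value, "n": c.n,
                })
            except (FitInputError, ZeroVarianceError) as exc:
                warnings.append(
                    f"correlation skipped for {power:g} W/{cf:g} g {other}: {exc}"
                )
        # Pop trend uses ALL valid records (incidence includes pop lesions).
        pop_subset = [r for r in valid
                      if r.setting.power_w == power and r.setting.cf_g == cf]
        times = sorted({r.duration_s for r in pop_subset})
        if len(times) >= 2:
            succ = [sum(r.steam_pop for r in pop_subset if r.duration_s == t)
                    for t in times]
            tot = [sum(1 for r in pop_subset if r.duration_s == t) for t in times]
            try:
                tr = inference.cochran_armitage_trend(succ, tot, scores=times)
                trend_rows.append({
                    "power_w": power, "cf_g": cf,
                    "z": tr.z_statistic, "p_value": tr.p_value,
                    "n_pops": int(sum(succ)), "n_total": int(sum(tot)),
                    "significant": tr.p_value < 0.05,
                })
            except ZeroVarianceError as exc:
                warnings.append(f"trend skipped for {power:g} W/{cf:g} g: {exc}")

    for w in warnings:
        logger.warning("%s", w)
    return SummaryReport(
        decay_table=pd.DataFrame(
            decay_rows, columns=["power_w", "cf_g", "response", "t90_s", "method"]
        ),
        threshold_table=pd.DataFrame(
            threshold_rows,
            columns=["power_w", "cf_g", "threshold_mm", "time_s", "status"],
        ),
        correlation_table=pd.DataFrame(
            corr_rows, columns=["power_w", "cf_g", "response", "r", "p_value", "n"]
        ),
        trend_table=pd.DataFrame(
            trend_rows,
            columns=["power_w", "cf_g", "z", "p_value", "n_pops", "n_total",
                     "significant"],
        ),
        fit_diagnostics=pd.DataFrame(
            diag_rows,
            columns=["power_w", "cf_g", "response", "model", "r_squared",
                     "n_points", "converged", "degenerate", "message"],
        ),
        fits=fits,
        records=list(valid),
        warnings=warnings,
    )


def _markdown_table(df: pd.DataFrame) -> str:
    if df.empty:
        return "_(empty)_\n"
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = []
        for v in row:
            cells.append(f"{v:.4g}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def render_report(
    report: SummaryReport,
    outdir: str | Path,
    fmt: str = "csv",
    plots: bool = False,
) -> list[Path]:
    """Write the report tables to ``outdir`` as CSV or one markdown summary.

    With ``plots=True`` additionally writes one response-versus-time
    figure per setting/response with the fitted curve and the t90
    boundary marked (requires the fits, i.e. a report produced in this
    process).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "csv":
        for name in REPORT_TABLES:
            path = outdir / f"{name}.csv"
            getattr(report, name).to_csv(path, index=False, float_format="%.10g")
            written.append(path)
    elif fmt == "md":
        parts = ["# Ablation kinetics summary\n"]
        titles = {
            "decay_table": "Time to 90% decay of peak dY/dt (s)",
            "threshold_table": "Time to reach the depth threshold (s)",
            "correlation_table": "LI drop vs lesion metrics (Pearson)",
            "trend_table": "Steam-pop incidence trend (Cochran-Armitage)",
            "fit_diagnostics": "Fit diagnostics",
        }
        for name in REPORT_TABLES:
            parts.append(f"## {titles[name]}\n")
            parts.append(_markdown_table(getattr(report, name)))
        path = outdir / "summary.md"
        path.write_text("\n".join(parts))
        written.append(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; supported formats: csv, md")
    if plots:
        written.extend(_render_plots(report, outdir))
    return written


def _render_plots(report: SummaryReport, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for (power, cf, resp), fit in sorted(report.fits.items()):
        subset = [r for r in report.records
                  if r.setting.power_w == power and r.setting.cf_g == cf]
        t = np.array([r.duration_s for r in subset])
        y = np.array([inference.RESPONSE_GETTERS[resp](r) for r in subset])
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(t, y, "o", alpha=0.5, label="data")
        if fit.converged:
            grid = np.linspace(0, max(t) * 1.05, 200)
            ax.plot(grid, growth.predict(fit, grid), "-", label="fit")
            if fit.model == growth.MODEL_ONE_PHASE and not fit.degenerate:
                t90 = decay.time_to_90_decay(fit).t90
                if t90 <= grid[-1]:
                    ax.axvline(t90, ls="--", color="gray", label="t90")
        ax.set_xlabel("RF delivery time (s)")
        ax.set_ylabel(resp)
        ax.set_title(f"{power:g} W / {cf:g} g — {resp}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"fit_{power:g}W_{cf:g}g_{resp}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
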