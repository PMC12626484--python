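"""End-to-end method-comparison pipeline and report rendering.

For every volumetry method in a cohort: calibrate the dry-weight correction
factor on the grid, apply it, then run the agreement battery (error-ratio
summaries before and after correction, Pearson r with CI, OLS regression,
modified Bland-Altman, ICC) and the mean volumetric ratios; finally compare
the methods' correlations with AGW pairwise via Steiger's z.

The report serialises losslessly to JSON; CSV rendering emits one grid
table per method plus a one-row-per-method summary; text rendering rounds
for reading (factors 2 dp, percentages and grams 2 dp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import calibration as cal
from .cohort import Cohort
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["GridSpec", "MethodReport", "MethodComparisonReport",
           "run_comparison", "render_report", "report_to_dict"]


@dataclass
class GridSpec:
    """Factor-grid bounds for calibration."""

    lo: float = cal.DEFAULT_LO
    hi: float = cal.DEFAULT_HI
    step: float = cal.DEFAULT_STEP


@dataclass
class MethodReport:
    """Everything computed for one volumetry method."""

    method: str
    calibration: cal.CalibrationResult
    pre_error: agr.ErrorRatioSummary
    post_error: agr.ErrorRatioSummary
    correlation: agr.CorrelationResult
    regression: agr.RegressionFit
    bland_altman: agr.BlandAltmanResult
    icc: agr.IccResult
    #: right lobe / total liver, mean of per-donor ratios (%), if totals present
    mean_of_ratios: float | None = None
    #: mean right volume / mean total volume (%), if totals present
    ratio_of_means: float | None = None


@dataclass
class CorrelationComparison:
    """Steiger z test for one pair of methods (correlations share AGW)."""

    method_a: str
    method_b: str
    r_a: float
    r_b: float
    r_ab: float
    z: float
    p_value: float


@dataclass
class MethodComparisonReport:
    n: int
    methods: list[str]
    per_method: dict[str, MethodReport]
    correlation_comparisons: list[CorrelationComparison]
    metadata: dict = field(default_factory=dict)


def _config_hash(options: dict) -> str:
    payload = json.dumps(options, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_comparison(cohort: Cohort, grid: GridSpec | None = None,
                   pre_correction: bool = False,
                   icc_variant: str = "A-1",
                   timestamp: bool = True) -> MethodComparisonReport:
    """Run calibrate -> correct -> evaluate for every method in the cohort.

    Deterministic given the cohort and options.  The agreement battery runs
    on corrected volumes by default; ``pre_correction=True`` evaluates the
    raw estimates instead (the calibration is still reported).
    """
    if cohort.n < 2:
        raise InputError("method comparison needs at least 2 donors")
    grid = grid or GridSpec()
    agw = cohort.agw()

    per_method: dict[str, MethodReport] = {}
    for m in cohort.methods:
        egv = cohort.right_volumes(m)
        try:
            result = cal.calibrate_method(egv, agw, method=m,
                                          lo=grid.lo, hi=grid.hi, step=grid.step)
            if result.at_boundary:
                logger.warning("%s: optimal factor %.2f at grid boundary", m, result.c_opt)
            if result.tie_count > 1:
                logger.warning("%s: %d grid points tie at the optimum", m, result.tie_count)
            c = result.c_opt
            corrected = cal.apply_correction(c, egv)
            evaluated = egv if pre_correction else corrected
            per_method[m] = MethodReport(
                method=m,
                calibration=result,
                pre_error=agr.summarize(agr.error_ratio(egv, agw)),
                post_error=agr.summarize(agr.error_ratio(corrected, agw)),
                correlation=agr.pearson_ci(evaluated, agw),
                regression=agr.ols_fit(evaluated, agw),
                bland_altman=agr.bland_altman(evaluated, agw),
                icc=agr.icc_two_way(evaluated, agw, variant=icc_variant),
            )
        except Exception as exc:
            raise type(exc)(f"method {m!r}: {exc}") from exc
        totals = cohort.total_volumes(m)
        if totals is not None:
            rights = cohort.right_volumes(m)
            per_method[m].mean_of_ratios = float((rights / totals).mean() * 100.0)
            per_method[m].ratio_of_means = float(rights.mean() / totals.mean() * 100.0)

    comparisons = []
    for i, ma in enumerate(cohort.methods):
        for mb in cohort.methods[i + 1:]:
            r_a = per_method[ma].correlation.r
            r_b = per_method[mb].correlation.r
            r_ab = float(np.corrcoef(cohort.right_volumes(ma),
                                     cohort.right_volumes(mb))[0, 1])
            if max(abs(r_a), abs(r_b), abs(r_ab)) >= 1.0 - 1e-12:
                logger.warning("skipping correlation comparison %s vs %s: "
                               "a correlation is degenerate (|r| = 1)", ma, mb)
                continue
            z, p = agr.compare_dependent_correlations(r_a, r_b, r_ab, cohort.n)
            comparisons.append(CorrelationComparison(
                method_a=ma, method_b=mb, r_a=r_a, r_b=r_b, r_ab=r_ab,
                z=z, p_value=p))

    options = {"grid": dataclasses.asdict(grid), "pre_correction": pre_correction,
               "icc_variant": icc_variant}
    metadata = {
        "config_hash": _config_hash(options),
        "options": options,
        "statistic_notes": {
            "correlation_comparison": "Steiger z, dependent correlations sharing AGW",
            "icc": per_method[cohort.methods[0]].icc.model,
        },
    }
    if timestamp:
        metadata["timestamp"] = datetime.now(timezone.utc).isoformat()
    return MethodComparisonReport(n=cohort.n, methods=list(cohort.methods),
                                  per_method=per_method,
                                  correlation_comparisons=comparisons,
                                  metadata=metadata)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def report_to_dict(report: MethodComparisonReport) -> dict:
    """Lossless plain-dict form of the report (JSON-serialisable)."""
    return _to_jsonable(report)


def _summary_frame(report: MethodComparisonReport) -> pd.DataFrame:
    rows = []
    for m in report.methods:
        r = report.per_method[m]
        rows.append({
            "method": m,
            "n": report.n,
            "c_opt": r.calibration.c_opt,
            "objective_at_opt": r.calibration.objective_at_opt,
            "pre_error_mean_pct": r.pre_error.mean,
            "pre_error_sd_pct": r.pre_error.sd,
            "post_error_mean_pct": r.post_error.mean,
            "post_error_sd_pct": r.post_error.sd,
            "r": r.correlation.r,
            "r_ci_low": r.correlation.ci_low,
            "r_ci_high": r.correlation.ci_high,
            "r_squared": r.regression.r_squared,
            "se": r.regression.se_resid,
            "intercept": r.regression.intercept,
            "slope": r.regression.slope,
            "md": r.bland_altman.mean_diff,
            "loa_low": r.bland_altman.loa_low,
            "loa_high": r.bland_altman.loa_high,
            "icc": r.icc.icc,
            "icc_ci_low": r.icc.ci_low,
            "icc_ci_high": r.icc.ci_high,
            "mean_of_ratios_pct": r.mean_of_ratios,
            "ratio_of_means_pct": r.ratio_of_means,
        })
    return pd.DataFrame(rows)


def render_report(report: MethodComparisonReport, format: str, out_dir) -> list[Path]:
    """Write the report; returns the paths written.

    ``json``: one lossless file ``report.json``.  ``csv``: ``summary.csv``
    (one row per method) plus ``grid_<method>.csv`` factor/objective tables.
    ``text``: ``report.txt`` with rounded values.
    """
    if not report.methods:
        raise InputError("report contains no methods")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if format == "json":
        path = out_dir / "report.json"
        path.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True))
        written.append(path)
    elif format == "csv":
        path = out_dir / "summary.csv"
        _summary_frame(report).to_csv(path, index=False)
        written.append(path)
        for m in report.methods:
            g = report.per_method[m].calibration.grid
            gpath = out_dir / f"grid_{m}.csv"
            pd.DataFrame({"factor": np.round(g.factors, 2),
                          "sum_abs_diff": g.objective}).to_csv(gpath, index=False)
            written.append(gpath)
    elif format == "text":
        lines = [f"Method comparison report  (n = {report.n} donors)", ""]
        for m in report.methods:
            r = report.per_method[m]
            lines += [
                f"[{m}]",
                f"  correction factor       {r.calibration.c_opt:.2f}"
                + ("  (grid boundary)" if r.calibration.at_boundary else "")
                + (f"  ({r.calibration.tie_count} ties)" if r.calibration.tie_count > 1 else ""),
                f"  error ratio pre -> post {r.pre_error.mean:.2f}% +/- {r.pre_error.sd:.2f}%"
                f" -> {r.post_error.mean:.2f}% +/- {r.post_error.sd:.2f}%",
                f"  Pearson r (95% CI)      {r.correlation.r:.3f}"
                f" ({r.correlation.ci_low:.3f}-{r.correlation.ci_high:.3f})",
                f"  regression              AGW = {r.regression.intercept:.3f}"
                f" + {r.regression.slope:.3f} x EGV"
                f"  (R^2 = {r.regression.r_squared:.3f}, SE = {r.regression.se_resid:.2f} g)",
                f"  Bland-Altman            MD {r.bland_altman.mean_diff:.2f} g,"
                f" LOA {r.bland_altman.loa_low:.2f} to {r.bland_altman.loa_high:.2f} g",
                f"  ICC                     {r.icc.icc:.3f}"
                f" ({r.icc.ci_low:.3f}-{r.icc.ci_high:.3f})",
            ]
            if r.mean_of_ratios is not None:
                lines.append(f"  right/total ratio       {r.mean_of_ratios:.2f}%"
                             f" (mean of ratios), {r.ratio_of_means:.2f}% (ratio of means)")
            lines.append("")
        if report.correlation_comparisons:
            lines.append("Correlation comparisons (Steiger z):")
            for cc in report.correlation_comparisons:
                lines.append(f"  {cc.method_a} vs {cc.method_b}: "
                             f"z = {cc.z:.3f}, p = {cc.p_value:.3f}")
        path = out_dir / "report.txt"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    else:
        raise InputError(f"unknown report format {format!r}")
    return written
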