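"""Accuracy and agreement statistics between estimated and actual graft weight.

Per-donor statistics
    difference      EGV - AGW (mL vs g treated 1:1)
    error ratio     (EGV - AGW) / AGW * 100%

Agreement battery (typically on corrected EGV)
    Pearson r with Fisher-z confidence interval
    ordinary least squares of AGW on EGV (R^2, residual SE)
    modified Bland-Altman: mean difference and mean +/- 1.96 SD limits of
        agreement, with the gold-standard AGW as the reference axis
    intraclass correlation, two-way model, absolute agreement, single
        measures — McGraw & Wong ICC(A,1) — with F-based confidence interval
    Steiger's z for comparing two dependent correlations that share AGW

Applying a correction factor ``c`` transforms the error-ratio summary
exactly: ``mean_post = (c*(1 + mean_pre/100) - 1)*100`` and
``sd_post = c*sd_pre``; Pearson r, R^2 and the r confidence interval are
invariant under any positive ``c``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NumericalError

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorRatioSummary",
    "CorrelationResult",
    "RegressionFit",
    "BlandAltmanResult",
    "IccResult",
    "difference",
    "error_ratio",
    "summarize",
    "corrected_error_summary",
    "pearson_ci",
    "ols_fit",
    "bland_altman",
    "icc_two_way",
    "compare_dependent_correlations",
]


def _check_pair(a, b, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise InputError("inputs must be 1-d sequences of equal length")
    if a.size < min_n:
        raise InputError(f"need at least {min_n} observations, got {a.size}")
    return a, b


@dataclass
class ErrorRatioSummary:
    """Mean and sample SD (n-1 denominator) of per-donor percentages."""

    per_donor: np.ndarray
    mean: float
    sd: float
    n: int


@dataclass
class CorrelationResult:
    """Pearson correlation with Fisher-z confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95


@dataclass
class RegressionFit:
    """OLS of AGW (y, grams) on EGV (x, mL): AGW = intercept + slope*EGV."""

    intercept: float
    slope: float
    r_squared: float
    se_resid: float
    n: int


@dataclass
class BlandAltmanResult:
    """Mean difference and limits of agreement of estimate minus reference."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float = 1.96
    n: int = 0


@dataclass
class IccResult:
    """Intraclass correlation between estimate and reference series."""

    icc: float
    ci_low: float
    ci_high: float
    model: str
    n: int
    k: int = 2


def difference(est, agw) -> np.ndarray:
    """Elementwise estimate minus reference (mL against g, 1:1)."""
    est, agw = _check_pair(est, agw)
    return est - agw


def error_ratio(est, agw) -> np.ndarray:
    """Per-donor percentage error (est - agw)/agw * 100."""
    est, agw = _check_pair(est, agw)
    if np.any(agw <= 0):
        raise InputError("all reference weights must be positive")
    return (est - agw) / agw * 100.0


def summarize(values) -> ErrorRatioSummary:
    """Mean and sample SD of a percentage vector."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise InputError("values must be a 1-d sequence")
    if values.size < 2:
        raise NumericalError("sample SD undefined for fewer than 2 values")
    return ErrorRatioSummary(
        per_donor=values,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n=int(values.size),
    )


def corrected_error_summary(c: float, mean_pre: float, sd_pre: float) -> tuple[float, float]:
    """Error-ratio summary after applying a correction factor, in closed form.

    Because the corrected ratio satisfies
    ``1 + ratio_post/100 = c*(1 + ratio_pre/100)`` donor by donor, the mean
    transforms as ``(c*(1 + mean_pre/100) - 1)*100`` and the SD scales to
    ``c*sd_pre``.
    """
    if c <= 0:
        raise InputError(f"correction factor must be positive, got {c}")
    return (c * (1.0 + mean_pre / 100.0) - 1.0) * 100.0, c * sd_pre


def pearson_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson correlation with a Fisher z-transform confidence interval.

    ``tanh(atanh(r) +/- z_level/sqrt(n-3))``.  A perfect correlation gives a
    degenerate (clamped) interval with a logged warning.
    """
    x, y = _check_pair(x, y, min_n=4)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NumericalError("correlation undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-14:
        logger.warning("|r| = 1: confidence interval clamped to the point estimate")
        return CorrelationResult(r=r, ci_low=r, ci_high=r, n=int(x.size), level=level)
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    half = z_crit / np.sqrt(x.size - 3)
    z = np.arctanh(r)
    return CorrelationResult(r=r, ci_low=float(np.tanh(z - half)),
                             ci_high=float(np.tanh(z + half)),
                             n=int(x.size), level=level)


def ols_fit(x, y) -> RegressionFit:
    """Least-squares line y = intercept + slope*x with R^2 and residual SE.

    ``se_resid = sqrt(SSE/(n-2))``, the regression standard error in the
    units of y (grams when y is AGW).
    """
    x, y = _check_pair(x, y, min_n=3)
    if np.ptp(x) == 0:
        raise NumericalError("degenerate design: x is constant")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sse = float(resid @ resid)
    return RegressionFit(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        se_resid=float(np.sqrt(sse / (x.size - 2))),
        n=int(x.size),
    )


def bland_altman(est, agw, multiplier: float = 1.96) -> BlandAltmanResult:
    """Modified Bland-Altman summary of est - agw differences.

    "Modified" refers to plotting differences against the gold-standard AGW
    rather than the pairwise mean; the mean difference and limits of
    agreement (mean +/- multiplier*SD, sample SD) do not depend on that
    axis choice.
    """
    est, agw = _check_pair(est, agw, min_n=2)
    d = est - agw
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean_diff=md, sd_diff=sd,
                             loa_low=md - multiplier * sd,
                             loa_high=md + multiplier * sd,
                             multiplier=multiplier, n=int(d.size))


_ICC_VARIANTS = {"A-1": "ICC(A,1)", "C-1": "ICC(C,1)"}
_ICC_MODEL_DESC = {
    "A-1": "two-way mixed effects, absolute agreement, single measures",
    "C-1": "two-way mixed effects, consistency, single measures",
}


def icc_two_way(est, agw, variant: str = "A-1") -> IccResult:
    """Intraclass correlation between the two series (donors x 2 raters).

    The default is McGraw & Wong's ICC(A,1): two-way model, absolute
    agreement, single measures,

        (MS_rows - MS_err) / (MS_rows + (k-1)MS_err + (k/n)(MS_cols - MS_err)),

    with the F-distribution confidence interval; computed via
    :func:`pingouin.intraclass_corr`.  ``variant="C-1"`` gives the
    consistency form.  When the interval is undefined (perfect agreement,
    infinite F) it is clamped to the point estimate.
    """
    est, agw = _check_pair(est, agw, min_n=3)
    if variant not in _ICC_VARIANTS:
        raise InputError(f"unknown ICC variant {variant!r}; use one of {list(_ICC_VARIANTS)}")
    if np.ptp(est) == 0 and np.ptp(agw) == 0 and est[0] == agw[0]:
        raise NumericalError("ICC undefined: zero total variance")

    import pingouin as pg

    n = est.size
    long = pd.DataFrame({
        "targets": np.repeat(np.arange(n), 2),
        "raters": np.tile(["est", "ref"], n),
        "ratings": np.column_stack([est, agw]).ravel(),
    })
    saved = dict(pg.options)
    pg.options["round"] = None
    pg.options.pop("round.column.CI95", None)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pg.intraclass_corr(long, targets="targets", raters="raters",
                                       ratings="ratings")
    finally:
        pg.options.clear()
        pg.options.update(saved)
    row = table.set_index("Type").loc[_ICC_VARIANTS[variant]]
    icc = float(row["ICC"])
    ci = np.asarray(row["CI95"], dtype=float)
    if not np.all(np.isfinite(ci)):
        logger.warning("ICC confidence interval undefined (degenerate data); "
                       "clamped to the point estimate")
        ci = np.array([icc, icc])
    return IccResult(icc=icc, ci_low=float(min(ci[0], icc)),
                     ci_high=float(max(ci[1], icc)),
                     model=_ICC_MODEL_DESC[variant], n=int(n), k=2)


def compare_dependent_correlations(r12: float, r13: float, r23: float,
                                   n: int) -> tuple[float, float]:
    """Steiger's z for two dependent correlations sharing one variable.

    Tests H0: rho(1,2) = rho(1,3) given the correlation r23 between the two
    non-shared variables (here variable 1 is AGW and 2, 3 are two methods'
    EGVs).  Uses the Fisher-z statistic with the Dunn & Clark covariance and
    Steiger's pooled-correlation simplification; returns (z, two-sided p).
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise InputError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n < 10:
        raise InputError(f"n must be at least 10, got {n}")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rm2 = (r12**2 + r13**2) / 2.0
    f = min((1.0 - r23) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - r23) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
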