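"""Dry-weight correction factor estimation.

The calibration objective is the total absolute difference between
corrected volume estimates and actual graft weights,

    S(c) = sum_i |c * EGV_i - AGW_i|,

minimised over a factor grid (default 0.80 to 0.95 in steps of 0.01, 16
candidates).  S is convex piecewise-linear in c with breakpoints at the
per-donor ratios AGW_i/EGV_i; its continuous minimiser is the weighted
median of those ratios with weights EGV_i, which :func:`exact_l1_factor`
computes in O(n log n) and which serves as the oracle for the grid search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "CorrectionGrid",
    "CalibrationResult",
    "sum_abs_diff",
    "correction_grid",
    "optimal_factor",
    "exact_l1_factor",
    "apply_correction",
    "calibrate_method",
]

#: Grid bounds used throughout unless overridden.
DEFAULT_LO = 0.80
DEFAULT_HI = 0.95
DEFAULT_STEP = 0.01

# relative tolerance for detecting flat (tied) stretches of the objective
_TIE_RTOL = 1e-9


@dataclass
class CorrectionGrid:
    """Candidate factors and the objective S(c) evaluated at each."""

    method: str
    factors: np.ndarray
    objective: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if self.factors.shape != self.objective.shape:
            raise InputError("factors and objective must be parallel lists")
        if np.any(np.diff(self.factors) <= 0):
            raise InputError("grid factors must be strictly increasing")


@dataclass
class CalibrationResult:
    """Grid-search outcome for one method.

    ``tie_count`` is the number of grid points attaining the minimum (the
    objective can be flat between ratio breakpoints); ties resolve to the
    smallest factor, the conservative choice for donor safety.
    ``at_boundary`` flags an argmin at either grid end, a hint that the true
    optimum may lie outside the searched range.
    """

    method: str
    c_opt: float
    objective_at_opt: float
    tie_count: int
    at_boundary: bool
    grid: CorrectionGrid


def _check_pair(egv, agw) -> tuple[np.ndarray, np.ndarray]:
    egv = np.asarray(egv, dtype=float)
    agw = np.asarray(agw, dtype=float)
    if egv.ndim != 1 or agw.ndim != 1 or egv.shape != agw.shape:
        raise InputError("egv and agw must be 1-d sequences of equal length")
    if egv.size == 0:
        raise InputError("empty input")
    return egv, agw


def sum_abs_diff(c: float, egv, agw) -> float:
    """Total absolute difference S(c) = sum |c*egv_i - agw_i|."""
    if c <= 0:
        raise InputError(f"correction factor must be positive, got {c}")
    egv, agw = _check_pair(egv, agw)
    return float(np.abs(c * egv - agw).sum())


def correction_grid(egv, agw, method: str = "",
                    lo: float = DEFAULT_LO, hi: float = DEFAULT_HI,
                    step: float = DEFAULT_STEP) -> CorrectionGrid:
    """Evaluate S(c) on the factor grid lo, lo+step, ..., hi.

    Grid points are built by integer index (``c_k = lo + k*step``) so that
    rounding error does not accumulate across steps; the defaults yield
    exactly 16 candidates.
    """
    egv, agw = _check_pair(egv, agw)
    if not (lo < hi) or step <= 0 or lo <= 0:
        raise InputError(f"degenerate grid: lo={lo}, hi={hi}, step={step}")
    n_pts = int(np.floor((hi - lo) / step + 1e-9)) + 1
    if n_pts < 2:
        raise InputError("grid must contain at least two points")
    # integer-index construction (no accumulated drift), snapped to the
    # decimal value each index represents
    factors = np.round(lo + step * np.arange(n_pts), 12)
    objective = np.abs(factors[:, None] * egv[None, :] - agw[None, :]).sum(axis=1)
    return CorrectionGrid(method=method, factors=factors, objective=objective)


def optimal_factor(grid: CorrectionGrid) -> CalibrationResult:
    """Argmin over the grid, ties broken toward the smallest factor."""
    if grid.factors.size == 0:
        raise InputError("empty grid")
    obj = grid.objective
    min_obj = float(obj.min())
    tol = _TIE_RTOL * max(1.0, abs(min_obj))
    ties = np.flatnonzero(obj <= min_obj + tol)
    idx = int(ties[0])
    return CalibrationResult(
        method=grid.method,
        c_opt=float(grid.factors[idx]),
        objective_at_opt=float(obj[idx]),
        tie_count=int(ties.size),
        at_boundary=idx == 0 or idx == grid.factors.size - 1,
        grid=grid,
    )


def exact_l1_factor(egv, agw) -> float:
    """Continuous minimiser of S(c): the EGV-weighted median of AGW/EGV.

    Sorts the per-donor ratios and walks the cumulative weight to the point
    where it first reaches half the total; when the optimum is a flat
    interval the lower endpoint is returned.
    """
    egv, agw = _check_pair(egv, agw)
    if np.any(egv <= 0):
        raise InputError("all egv values must be positive")
    ratios = agw / egv
    order = np.argsort(ratios, kind="stable")
    ratios = ratios[order]
    weights = egv[order]
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(ratios[idx])


def apply_correction(c: float, volumes) -> np.ndarray:
    """Scale volume estimates by the correction factor."""
    if c <= 0:
        raise InputError(f"correction factor must be positive, got {c}")
    return c * np.asarray(volumes, dtype=float)


def calibrate_method(egv, agw, method: str = "",
                     lo: float = DEFAULT_LO, hi: float = DEFAULT_HI,
                     step: float = DEFAULT_STEP) -> CalibrationResult:
    """Convenience wrapper: build the grid and pick the optimal factor."""
    return optimal_factor(correction_grid(egv, agw, method=method,
                                          lo=lo, hi=hi, step=step))
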