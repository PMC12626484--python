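"""Graft and donor safety screening.

Two thresholds guard a living-donor right-lobe transplant:

* the graft-to-recipient weight ratio, GRWR = graft weight (g) / recipient
  weight (g) x 100%, should be at least 0.8% to avoid small-for-size
  syndrome (SFSS); and
* the donor's remnant liver should be at least 30% (conservative; some
  centres require 40%) of the total liver volume.

Predicted GRWR uses the corrected volume estimate (c * EGV) in place of the
graft weight; it scales exactly by c relative to the uncorrected value.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort
from .errors import InputError

__all__ = ["SafetyAssessment", "grwr", "sfss_flag", "lobe_ratios", "screen_cohort"]

DEFAULT_GRWR_MIN = 0.8
DEFAULT_REMNANT_MIN = 30.0


@dataclass
class SafetyAssessment:
    """Threshold screening outcome for one donor under one method."""

    donor_id: str
    method: str
    grwr_predicted: float | None
    grwr_actual: float | None
    sfss_flag: bool | None
    right_ratio: float | None
    remnant_ratio: float | None
    remnant_flag: bool | None
    grwr_min: float = DEFAULT_GRWR_MIN
    remnant_min: float = DEFAULT_REMNANT_MIN


def grwr(graft_weight: float, recipient_weight: float) -> float:
    """GRWR in percent from graft weight (g) and recipient weight (kg)."""
    if graft_weight <= 0 or recipient_weight <= 0:
        raise InputError("graft and recipient weights must be positive")
    return graft_weight / (recipient_weight * 1000.0) * 100.0


def sfss_flag(grwr_value: float, threshold: float = DEFAULT_GRWR_MIN) -> bool:
    """True when GRWR falls strictly below the small-for-size threshold."""
    if grwr_value < 0:
        raise InputError("GRWR cannot be negative")
    return grwr_value < threshold


def lobe_ratios(right: float, total: float,
                remnant_min: float = DEFAULT_REMNANT_MIN) -> tuple[float, float, bool]:
    """Right-lobe and remnant percentages of total liver volume.

    Returns ``(right_ratio, remnant_ratio, remnant_flag)`` where the flag is
    raised when the remnant falls strictly below ``remnant_min`` percent.
    """
    if right <= 0 or total <= 0:
        raise InputError("volumes must be positive")
    if right > total:
        raise InputError(f"right lobe {right} exceeds total liver {total}")
    right_ratio = right / total * 100.0
    remnant_ratio = 100.0 - right_ratio
    return right_ratio, remnant_ratio, remnant_ratio < remnant_min


def screen_cohort(cohort: Cohort, factors: dict[str, float],
                  grwr_min: float = DEFAULT_GRWR_MIN,
                  remnant_min: float = DEFAULT_REMNANT_MIN) -> pd.DataFrame:
    """Screen every donor under every method, one row per donor x method.

    ``factors`` maps method label to its correction factor; predicted GRWR
    uses the corrected right-lobe estimate, actual GRWR the measured graft
    weight.  GRWR fields are NaN when the recipient weight is missing, lobe
    ratios when the total volume is missing.
    """
    missing = [m for m in cohort.methods if m not in factors]
    if missing:
        raise InputError(f"no correction factor for methods {missing}")
    rows = []
    for rec in cohort.records:
        for m in cohort.methods:
            c = factors[m]
            if c <= 0:
                raise InputError(f"correction factor for {m!r} must be positive")
            v = rec.volumes[m]
            corrected = c * v.right_lobe
            if rec.recipient_weight is not None:
                pred = grwr(corrected, rec.recipient_weight)
                actual = grwr(rec.agw, rec.recipient_weight)
                flag = sfss_flag(pred, grwr_min)
            else:
                pred = actual = flag = None
            if v.total_liver is not None:
                rr, rem, rflag = lobe_ratios(v.right_lobe, v.total_liver, remnant_min)
            else:
                rr = rem = rflag = None
            rows.append({
                "donor_id": rec.donor_id, "method": m,
                "corrected_egv_ml": corrected,
                "grwr_predicted_pct": pred, "grwr_actual_pct": actual,
                "sfss_flag": flag,
                "right_ratio_pct": rr, "remnant_ratio_pct": rem,
                "remnant_flag": rflag,
            })
    return pd.DataFrame(rows)
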