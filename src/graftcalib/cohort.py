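"""Donor-cohort data model and delimited-text I/O.

A cohort is one row per living liver donor: the actual graft weight (AGW,
grams, weighed on the back table after procurement) together with the
estimated right-lobe volume (and optionally total-liver volume, mL) from one
or more CT volumetry methods, plus optional recipient weight and donor
covariates.

File dialect: UTF-8 delimited text (comma by default), header required,
decimal point. Columns::

    donor_id, agw_g, <method>_right_ml[, <method>_total_ml]...,
    recipient_kg, age, sex, bmi, op_method

Volumes in mL and weights in g are treated as numerically interchangeable
(1 mL = 1 g working premise); no unit autodetection is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortFormatError, EmptyCohortError, InputError

logger = logging.getLogger(__name__)

_RIGHT_SUFFIX = "_right_ml"
_TOTAL_SUFFIX = "_total_ml"
_COVARIATE_COLS = ("age", "sex", "bmi", "op_method")
_NA_STRINGS = {"", "NA", "na", "NaN", "nan", "N/A"}


@dataclass
class MethodVolumes:
    """Volume estimates from one volumetry method for one donor."""

    right_lobe: float
    total_liver: float | None = None


@dataclass
class DonorRecord:
    """One donor: gold-standard graft weight plus per-method volume estimates.

    Parameters
    ----------
    donor_id : str
        Identifier, unique within a cohort by convention (not enforced).
    agw : float
        Actual graft weight in grams; must be positive.
    volumes : dict[str, MethodVolumes]
        Mapping from volumetry-method label to its estimates.
    recipient_weight : float, optional
        Recipient body weight in kg, used for GRWR screening.
    covariates : dict, optional
        Donor covariates (age, sex, bmi, op_method).
    """

    donor_id: str
    agw: float
    volumes: dict[str, MethodVolumes]
    recipient_weight: float | None = None
    covariates: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """Ordered collection of donor records sharing a common method list."""

    records: list[DonorRecord]
    methods: list[str]
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.records)

    def agw(self) -> np.ndarray:
        """Actual graft weights (g) in record order."""
        return np.array([r.agw for r in self.records], dtype=float)

    def right_volumes(self, method: str) -> np.ndarray:
        """Estimated right-lobe volumes (mL) for one method, in record order."""
        self._check_method(method)
        return np.array([r.volumes[method].right_lobe for r in self.records], dtype=float)

    def total_volumes(self, method: str) -> np.ndarray | None:
        """Total-liver volumes (mL) for one method, or None if any are absent."""
        self._check_method(method)
        totals = [r.volumes[method].total_liver for r in self.records]
        if any(t is None for t in totals):
            return None
        return np.array(totals, dtype=float)

    def recipient_weights(self) -> np.ndarray | None:
        """Recipient body weights (kg), or None if any are absent."""
        weights = [r.recipient_weight for r in self.records]
        if any(w is None for w in weights):
            return None
        return np.array(weights, dtype=float)

    def _check_method(self, method: str) -> None:
        if method not in self.methods:
            raise InputError(f"unknown method {method!r}; cohort has {self.methods}")


@dataclass
class ValidationReport:
    """Hard errors and soft warnings from :func:`validate_cohort`."""

    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in _NA_STRINGS:
        return None
    try:
        x = float(s)
    except ValueError:
        return None
    return x if np.isfinite(x) else None


def read_cohort(path, delimiter: str = ",") -> Cohort:
    """Read a cohort CSV, dropping unusable rows with a logged warning.

    Rows with a missing or unparsable AGW or right-lobe volume (for any
    method named in the header) are dropped, never imputed; the count of
    dropped rows is recorded on ``Cohort.n_dropped``.

    Raises
    ------
    CohortFormatError
        If the ``agw_g`` column or every method column is missing.
    EmptyCohortError
        If no usable rows remain.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortFormatError(f"cannot read cohort file {path}: {exc}") from exc

    if "agw_g" not in df.columns:
        raise CohortFormatError("required column 'agw_g' missing")
    methods = [c[: -len(_RIGHT_SUFFIX)] for c in df.columns if c.endswith(_RIGHT_SUFFIX)]
    if not methods:
        raise CohortFormatError(f"no '<method>{_RIGHT_SUFFIX}' column found")

    records: list[DonorRecord] = []
    n_dropped = 0
    for i, row in df.iterrows():
        agw = _parse_float(row.get("agw_g"))
        vols: dict[str, MethodVolumes] = {}
        usable = agw is not None
        for m in methods:
            right = _parse_float(row.get(m + _RIGHT_SUFFIX))
            if right is None:
                usable = False
                break
            total_col = m + _TOTAL_SUFFIX
            total = _parse_float(row.get(total_col)) if total_col in df.columns else None
            vols[m] = MethodVolumes(right_lobe=right, total_liver=total)
        if not usable:
            n_dropped += 1
            logger.warning("dropping row %d (%s): missing/unparsable AGW or volume",
                           i, row.get("donor_id", "?"))
            continue
        covars = {c: row[c] for c in _COVARIATE_COLS if c in df.columns and
                  str(row[c]).strip() not in _NA_STRINGS}
        for c in ("age", "bmi"):
            if c in covars:
                covars[c] = _parse_float(covars[c])
        donor_id = str(row["donor_id"]) if "donor_id" in df.columns else str(i)
        records.append(DonorRecord(
            donor_id=donor_id,
            agw=agw,
            volumes=vols,
            recipient_weight=_parse_float(row.get("recipient_kg")),
            covariates=covars,
        ))

    if not records:
        raise EmptyCohortError(f"no usable donor rows in {path}")
    if n_dropped:
        logger.warning("dropped %d of %d rows from %s", n_dropped, len(df), path)
    return Cohort(records=records, methods=methods, n_dropped=n_dropped)


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort in the standard dialect at full float precision.

    Column order is deterministic: donor_id, agw_g, then each method's
    right (and total, if any record has one), then recipient/covariate
    columns present anywhere in the cohort.
    """
    cols: dict[str, list] = {"donor_id": [], "agw_g": []}
    method_has_total = {m: any(r.volumes[m].total_liver is not None for r in cohort.records)
                        for m in cohort.methods}
    for m in cohort.methods:
        cols[m + _RIGHT_SUFFIX] = []
        if method_has_total[m]:
            cols[m + _TOTAL_SUFFIX] = []
    has_recipient = any(r.recipient_weight is not None for r in cohort.records)
    if has_recipient:
        cols["recipient_kg"] = []
    covar_present = [c for c in _COVARIATE_COLS
                     if any(c in r.covariates for r in cohort.records)]
    for c in covar_present:
        cols[c] = []

    for r in cohort.records:
        cols["donor_id"].append(r.donor_id)
        cols["agw_g"].append(repr(float(r.agw)))
        for m in cohort.methods:
            v = r.volumes[m]
            cols[m + _RIGHT_SUFFIX].append(repr(float(v.right_lobe)))
            if method_has_total[m]:
                cols[m + _TOTAL_SUFFIX].append(
                    "" if v.total_liver is None else repr(float(v.total_liver)))
        if has_recipient:
            cols["recipient_kg"].append(
                "" if r.recipient_weight is None else repr(float(r.recipient_weight)))
        for c in covar_present:
            val = r.covariates.get(c)
            if val is None:
                cols[c].append("")
            elif isinstance(val, float):
                cols[c].append(repr(val))
            else:
                cols[c].append(str(val))

    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)


def validate_cohort(cohort: Cohort,
                    agw_bounds: tuple[float, float] = (200.0, 2500.0),
                    grwr_bounds: tuple[float, float] = (0.3, 5.0)) -> ValidationReport:
    """Report-only plausibility and consistency checks.

    Hard errors: non-positive AGW or volumes; right lobe exceeding the total
    liver. Soft warnings: AGW outside ``agw_bounds`` grams, or actual GRWR
    outside ``grwr_bounds`` percent when a recipient weight is available.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    for r in cohort.records:
        if r.agw <= 0:
            errors.append(f"{r.donor_id}: non-positive AGW {r.agw}")
        elif not agw_bounds[0] <= r.agw <= agw_bounds[1]:
            warnings_.append(f"{r.donor_id}: AGW {r.agw} g outside plausible "
                             f"range {agw_bounds}")
        for m, v in r.volumes.items():
            if v.right_lobe <= 0:
                errors.append(f"{r.donor_id}/{m}: non-positive right-lobe volume")
            if v.total_liver is not None:
                if v.total_liver <= 0:
                    errors.append(f"{r.donor_id}/{m}: non-positive total volume")
                elif v.right_lobe > v.total_liver:
                    errors.append(f"{r.donor_id}/{m}: right lobe {v.right_lobe} "
                                  f"exceeds total {v.total_liver}")
        if r.recipient_weight is not None and r.recipient_weight > 0 and r.agw > 0:
            grwr_pct = r.agw / (r.recipient_weight * 1000.0) * 100.0
            if not grwr_bounds[0] <= grwr_pct <= grwr_bounds[1]:
                warnings_.append(f"{r.donor_id}: GRWR {grwr_pct:.2f}% outside "
                                 f"plausible range {grwr_bounds}")
    return ValidationReport(errors=errors, warnings=warnings_)
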