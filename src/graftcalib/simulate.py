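"""Synthetic donor-cohort generator.

Emulates the statistical structure of a right-lobe living-donor cohort so
that calibration and agreement analyses can be exercised end to end without
patient data:

* Actual graft weight (AGW) is lognormal, moment-matched to a target
  mean/SD (defaults 783.7 / 163.5 g).
* Each volumetry method overestimates the graft by the reciprocal of its
  true dry-weight correction factor ``c_m`` and adds multiplicative
  lognormal noise: ``EGV = (AGW / c_m) * exp(eps)``.
* The noise is centred at ``-sigma_m**2`` on the log scale so that the
  population minimiser of the L1 calibration objective
  ``sum(|c*EGV - AGW|)`` — the EGV-weighted median of the AGW/EGV ratios —
  equals ``c_m`` exactly.  With zero-mean noise the EGV weights tilt the
  ratio distribution and the L1 optimum would sit at ``c_m*exp(-sigma**2)``
  instead of ``c_m``.
* Total-liver volume is a fixed multiple of the right lobe (default
  1.553, i.e. a right/total ratio of ~64.4%).
* Recipient weight is normal, truncated below (default 35 kg), independent
  of AGW; defaults give a mean GRWR of ~1.24%.

Noise SDs are calibrated from a target Pearson correlation between EGV and
AGW via :func:`calibrate_noise_sd`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Cohort, DonorRecord, MethodVolumes
from .errors import InputError

__all__ = [
    "MethodSpec",
    "CohortParams",
    "lognormal_params_from_moments",
    "calibrate_noise_sd",
    "generate_cohort",
    "default_method_specs",
]

#: Default targets: AGW moments, GRWR-compatible recipient weights, and the
#: per-method true factors the analysis is expected to recover.
DEFAULT_AGW_MEAN = 783.7
DEFAULT_AGW_SD = 163.5
DEFAULT_TOTAL_OVER_RIGHT = 1.553
DEFAULT_RECIPIENT_MEAN = 63.2
DEFAULT_RECIPIENT_SD = 11.0
DEFAULT_RECIPIENT_MIN = 35.0
DEFAULT_TARGET_R = 0.82
DEFAULT_TRUE_FACTORS = {"automated": 0.89, "semi_automated": 0.82, "manual": 0.88}


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with the given linear mean and SD.

    ``sigma = sqrt(ln(1 + (sd/mean)**2))`` and ``mu = ln(mean) - sigma**2/2``.
    """
    if mean <= 0:
        raise InputError(f"lognormal mean must be positive, got {mean}")
    if sd < 0:
        raise InputError(f"sd must be non-negative, got {sd}")
    sigma = math.sqrt(math.log1p((sd / mean) ** 2))
    mu = math.log(mean) - sigma**2 / 2.0
    return mu, sigma


def calibrate_noise_sd(target_r: float, sigma_log_agw: float) -> float:
    """Log-scale noise SD yielding a target EGV–AGW Pearson correlation.

    Exact for the correlation of the logs
    (``r = sigma_A / sqrt(sigma_A**2 + sigma_m**2)``); a close approximation
    for the linear-scale Pearson r at the coefficients of variation seen in
    graft volumetry.
    """
    if not 0.0 < target_r <= 1.0:
        raise InputError(f"target_r must be in (0, 1], got {target_r}")
    if sigma_log_agw < 0:
        raise InputError("sigma_log_agw must be non-negative")
    return sigma_log_agw * math.sqrt(1.0 / target_r**2 - 1.0)


@dataclass
class MethodSpec:
    """One volumetry method's generative parameters.

    ``true_factor`` is the dry-weight correction factor the method should
    calibrate to (multiplicative bias is its reciprocal); ``noise_sd`` is
    the log-scale SD of the multiplicative measurement noise.
    """

    true_factor: float
    noise_sd: float

    def validate(self) -> None:
        if not 0.0 < self.true_factor <= 1.5:
            raise InputError(f"true_factor must be in (0, 1.5], got {self.true_factor}")
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be non-negative, got {self.noise_sd}")


def default_method_specs(target_r: float = DEFAULT_TARGET_R,
                         agw_mean: float = DEFAULT_AGW_MEAN,
                         agw_sd: float = DEFAULT_AGW_SD) -> dict[str, MethodSpec]:
    """Three methods with the canonical factors 0.89/0.82/0.88 and noise
    calibrated so that r(EGV, AGW) is about ``target_r``."""
    _, sigma_a = lognormal_params_from_moments(agw_mean, agw_sd)
    sd = calibrate_noise_sd(target_r, sigma_a)
    return {label: MethodSpec(true_factor=c, noise_sd=sd)
            for label, c in DEFAULT_TRUE_FACTORS.items()}


@dataclass
class CohortParams:
    """Generative parameters for a synthetic donor cohort."""

    n: int = 100
    agw_mean: float = DEFAULT_AGW_MEAN
    agw_sd: float = DEFAULT_AGW_SD
    method_specs: dict[str, MethodSpec] = field(default_factory=default_method_specs)
    total_over_right: float = DEFAULT_TOTAL_OVER_RIGHT
    recipient_mean: float = DEFAULT_RECIPIENT_MEAN
    recipient_sd: float = DEFAULT_RECIPIENT_SD
    recipient_min: float = DEFAULT_RECIPIENT_MIN
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise InputError(f"n must be >= 1, got {self.n}")
        for name, val in (("agw_mean", self.agw_mean), ("agw_sd", self.agw_sd),
                          ("recipient_mean", self.recipient_mean),
                          ("recipient_sd", self.recipient_sd)):
            if val < 0 or (name.endswith("mean") and val <= 0):
                raise InputError(f"{name} must be positive, got {val}")
        if self.total_over_right <= 1.0:
            raise InputError("total_over_right must exceed 1")
        if not self.method_specs:
            raise InputError("at least one method spec is required")
        for spec in self.method_specs.values():
            spec.validate()


def generate_cohort(params: CohortParams, seed: int | None = None) -> Cohort:
    """Draw a synthetic cohort; deterministic given (params, seed).

    ``seed`` overrides ``params.seed`` when given.  One root seed sequence
    drives all draws; per-method sub-streams are spawned deterministically
    in method order, so adding a method does not perturb the others.
    """
    params.validate()
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    agw_ss, recip_ss, *method_ss = root.spawn(2 + len(params.method_specs))

    mu, sigma_a = lognormal_params_from_moments(params.agw_mean, params.agw_sd)
    agw = np.random.default_rng(agw_ss).lognormal(mu, sigma_a, params.n)

    a = (params.recipient_min - params.recipient_mean) / params.recipient_sd
    recipient = stats.truncnorm.rvs(
        a, np.inf, loc=params.recipient_mean, scale=params.recipient_sd,
        size=params.n, random_state=np.random.default_rng(recip_ss))

    egv: dict[str, np.ndarray] = {}
    for (label, spec), ss in zip(params.method_specs.items(), method_ss):
        rng = np.random.default_rng(ss)
        if spec.noise_sd == 0.0:
            noise = np.ones(params.n)
        else:
            # centred at -sd^2 so the weighted-median L1 optimum equals true_factor
            noise = np.exp(rng.normal(-spec.noise_sd**2, spec.noise_sd, params.n))
        egv[label] = agw / spec.true_factor * noise

    methods = list(params.method_specs)
    records = []
    for i in range(params.n):
        vols = {m: MethodVolumes(right_lobe=float(egv[m][i]),
                                 total_liver=float(egv[m][i] * params.total_over_right))
                for m in methods}
        records.append(DonorRecord(
            donor_id=f"D{i + 1:04d}",
            agw=float(agw[i]),
            volumes=vols,
            recipient_weight=float(recipient[i]),
        ))
    return Cohort(records=records, methods=methods)
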