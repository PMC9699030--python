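"""Per-patient exposure metrics, toxicity rules and the composite outcome.

Exposure is summarized over the first three treatment cycles as the mean
end-of-infusion peak (Cmax), the mean pre-infusion trough (Cmin) and the
mean per-course AUC (dose/CL for a linear model).  Nephrotoxicity follows
the CTCAE creatinine rule (a rise of more than 50% over baseline and/or
more than 26 umol/L); severe ototoxicity is consumed as a CTCAE grade >= 3
flag.  The composite "clinical benefit" requires a CR/PR/SD RECIST response
together with the absence of both severe toxicities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayesfit import IndividualFit, Observation
from .pkcore import DosingEvent, simulate_profile

__all__ = [
    "RECIST_CLASSES",
    "ExposureMetrics",
    "OutcomeLabels",
    "PatientRecord",
    "MissingExposureError",
    "UndefinedProportionError",
    "nephrotoxicity_flag",
    "composite_outcome",
    "exposure_summary",
    "proportions_from_counts",
]

RECIST_CLASSES = ("CR", "PR", "SD", "PD")

#: creatinine thresholds of the CTCAE nephrotoxicity rule
CREATININE_REL_RISE = 0.5     # more than +50% over baseline
CREATININE_ABS_RISE = 26.0    # more than +26 umol/L over baseline

#: default next-course spacing used to place the trough of the last course
DEFAULT_COURSE_INTERVAL_H = 21 * 24.0


class MissingExposureError(ValueError):
    """No accepted fit and no observations to compute exposure from."""


class UndefinedProportionError(ZeroDivisionError):
    """Proportion requested over an empty denominator."""


@dataclass(frozen=True)
class ExposureMetrics:
    """Mean exposure over the first min(3, available) courses."""

    cmax_mean: float
    cmin_mean: float
    auc_mean: float
    cmax_per_course: tuple = ()
    cmin_per_course: tuple = ()
    auc_per_course: tuple = ()


@dataclass(frozen=True)
class OutcomeLabels:
    """Response class, toxicity flags and the derived composite benefit."""

    recist_class: str
    nephrotoxicity_severe: bool
    ototoxicity_severe: bool

    def __post_init__(self) -> None:
        if self.recist_class not in RECIST_CLASSES:
            raise ValueError(
                f"unknown RECIST class {self.recist_class!r}; expected one of "
                f"{RECIST_CLASSES}"
            )

    @property
    def clinical_benefit(self) -> bool:
        return composite_outcome(self.recist_class, self.nephrotoxicity_severe,
                                 self.ototoxicity_severe)


@dataclass
class PatientRecord:
    """Everything known about one patient."""

    patient_id: str
    covariates: dict
    regimen: list[DosingEvent]
    observations: list[Observation]
    baseline_creatinine: float
    creatinine_series: list[float]
    outcome: OutcomeLabels | None = None


# ---------------------------------------------------------------------------
# outcome rules
# ---------------------------------------------------------------------------

def nephrotoxicity_flag(baseline_creatinine: float, series: list[float]) -> bool:
    """CTCAE creatinine rule: any value > baseline*1.5 OR > baseline+26 umol/L.

    Both branches are strict ("more than").  An empty series cannot flag
    toxicity and returns False with a warning.
    """
    if baseline_creatinine <= 0:
        raise ValueError(f"baseline creatinine must be > 0, got {baseline_creatinine}")
    if len(series) == 0:
        warnings.warn("empty creatinine series: nephrotoxicity assumed absent",
                      stacklevel=2)
        return False
    arr = np.asarray(series, dtype=float)
    return bool(np.any(
        (arr > baseline_creatinine * (1.0 + CREATININE_REL_RISE))
        | (arr > baseline_creatinine + CREATININE_ABS_RISE)
    ))


def composite_outcome(recist_class: str, nephro_flag: bool, oto_flag: bool) -> bool:
    """Clinical benefit = CR/PR/SD response AND no severe nephro/ototoxicity."""
    if recist_class not in RECIST_CLASSES:
        raise ValueError(
            f"unknown RECIST class {recist_class!r}; expected one of {RECIST_CLASSES}"
        )
    return (recist_class in ("CR", "PR", "SD")) and not nephro_flag and not oto_flag


# ---------------------------------------------------------------------------
# exposure metrics
# ---------------------------------------------------------------------------

def exposure_summary(fits: list[IndividualFit | None],
                     regimen: list[DosingEvent],
                     observations: list[Observation] = (),
                     use_observed: bool = True,
                     max_courses: int = 3) -> ExposureMetrics:
    """Per-course Cmax / Cmin / AUC and their means over the first courses.

    For each course the model peak is the concentration at the infusion end
    (full superposition, so residual drug from earlier courses counts) and
    the model trough is the concentration immediately before the next
    infusion (the last course uses a 21-day horizon).  AUC is dose/CL.
    When ``use_observed`` is set, a measured peak or trough from routine
    monitoring replaces the model value for its course (TDM primacy) and
    model values fill the gaps.

    Parameters
    ----------
    fits : list of IndividualFit or None
        Per-course fits; a single-element list applies one fit to all
        courses.  ``None`` entries fall back to observed values.
    regimen : list of DosingEvent
        All dosing events for the patient, in chronological order.
    observations : list of Observation
        Measured troughs/peaks, matched to courses by ``course_index``.
    """
    if len(regimen) == 0:
        raise ValueError("regimen must contain at least one course")
    n_courses = min(max_courses, len(regimen))
    if len(fits) == 1:
        fits = list(fits) * len(regimen)

    obs_peak = {o.course_index: o.concentration for o in observations
                if o.kind == "peak"}
    obs_trough = {o.course_index: o.concentration for o in observations
                  if o.kind == "trough"}

    cmax, cmin, auc = [], [], []
    for k in range(n_courses):
        fit = fits[k] if k < len(fits) else None
        ev = regimen[k]
        trough_time = (regimen[k + 1].start if k + 1 < len(regimen)
                       else ev.start + DEFAULT_COURSE_INTERVAL_H)

        peak_obs = obs_peak.get(k) if use_observed else None
        # the trough drawn before infusion k+1 carries course_index k+1
        trough_obs = obs_trough.get(k + 1) if use_observed else None

        if fit is not None:
            model_peak = float(simulate_profile(fit.macros, regimen, [ev.end])[0])
            model_trough = float(simulate_profile(fit.macros, regimen,
                                                  [trough_time])[0])
            auc.append(ev.dose / fit.derived.CL)
            cmax.append(peak_obs if peak_obs is not None else model_peak)
            cmin.append(trough_obs if trough_obs is not None else model_trough)
        else:
            if peak_obs is None and trough_obs is None:
                raise MissingExposureError(
                    f"course {k}: no fit and no observations to compute exposure"
                )
            cmax.append(peak_obs if peak_obs is not None else 0.0)
            cmin.append(trough_obs if trough_obs is not None else 0.0)
            auc.append(float("nan"))

    return ExposureMetrics(
        cmax_mean=float(np.mean(cmax)),
        cmin_mean=float(np.mean(cmin)),
        auc_mean=float(np.nanmean(auc)) if not all(math.isnan(a) for a in auc)
        else float("nan"),
        cmax_per_course=tuple(cmax),
        cmin_per_course=tuple(cmin),
        auc_per_course=tuple(auc),
    )


def proportions_from_counts(yes: int, total: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if total <= 0:
        raise UndefinedProportionError("proportion undefined for total = 0")
    if not 0 <= yes <= total:
        raise ValueError(f"need 0 <= yes <= total, got yes={yes}, total={total}")
    return int(math.floor(100.0 * yes / total + 0.5))
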