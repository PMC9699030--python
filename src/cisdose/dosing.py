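"""Next-course dose individualization toward a target end-of-infusion peak.

Because the kinetics are linear, the dose that makes the end-of-infusion
concentration hit a target Cmax has a closed form: with u(T) the
individual per-mg end-of-infusion response and C_res the decayed residual
of every earlier dose at that moment,

    D* = (target - C_res) / u(T).

The default target is the middle of the therapeutic window (3.1 ug/mL for
the [2.1, 4.1] ug/mL window).  A day-21 trough simulation and a
validation-style report comparing simulated troughs, measured troughs and
proposed-versus-actual doses (with a paired t statistic) complete the
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesfit import IndividualFit, predict_trough
from .pkcore import DosingEvent, simulate_profile, unit_infusion_response

__all__ = [
    "DoseProposal",
    "DEFAULT_TARGET_CMAX",
    "propose_dose",
    "percent_change",
    "validation_report",
]

DEFAULT_TARGET_CMAX = 3.1       # ug/mL, middle of the [2.1, 4.1] window
DEFAULT_SPACING_H = 21 * 24.0   # default inter-course interval


@dataclass(frozen=True)
class DoseProposal:
    proposed_dose: float            #: mg (0 when infeasible)
    target_cmax: float              #: ug/mL
    predicted_trough_d21: float     #: ug/mL just before the next course
    predicted_cmax_at_proposed: float
    actual_dose: float | None
    percent_change: int | None      #: signed %, vs actual dose
    feasible: bool
    capped: bool = False
    uncapped_dose: float | None = None


def percent_change(actual: float, proposed: float) -> int:
    """Signed percentage change, rounded half away from zero."""
    if actual <= 0:
        raise ValueError(f"actual dose must be > 0, got {actual}")
    pct = 100.0 * (proposed - actual) / actual
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def propose_dose(fit: IndividualFit, prior_regimen: list[DosingEvent],
                 next_start: float, duration: float = 3.0,
                 target: float = DEFAULT_TARGET_CMAX,
                 actual_dose: float | None = None,
                 max_dose: float | None = None,
                 force: bool = False) -> DoseProposal:
    """Closed-form dose for the next course to reach ``target`` at its peak.

    ``next_start`` is the planned start of the next infusion (hours).  The
    residual concentration of all prior courses at the new peak time is
    subtracted from the target before inverting the unit response; when the
    residual alone exceeds the target the proposal is infeasible (dose 0).
    Fits that failed the precision-acceptance rule are rejected unless
    ``force`` is set.  An optional ``max_dose`` caps the proposal, with the
    uncapped value retained.
    """
    if target <= 0:
        raise ValueError(f"target Cmax must be > 0, got {target}")
    if not fit.accepted and not force:
        raise ValueError("fit failed precision acceptance; pass force=True "
                         "to dose on it anyway")
    for ev in prior_regimen:
        if ev.end > next_start:
            raise ValueError("next_start must fall after all prior infusions")

    t_peak = next_start + duration
    residual = float(simulate_profile(fit.macros, prior_regimen, [t_peak])[0])
    trough = float(simulate_profile(fit.macros, prior_regimen, [next_start])[0])
    u = float(unit_infusion_response(fit.macros, duration, duration))

    if residual >= target:
        return DoseProposal(
            proposed_dose=0.0, target_cmax=target, predicted_trough_d21=trough,
            predicted_cmax_at_proposed=residual, actual_dose=actual_dose,
            percent_change=(percent_change(actual_dose, 0.0)
                            if actual_dose else None),
            feasible=False,
        )
    dose = (target - residual) / u
    capped = max_dose is not None and dose > max_dose
    final = min(dose, max_dose) if capped else dose
    cmax = residual + final * u
    return DoseProposal(
        proposed_dose=float(final), target_cmax=target,
        predicted_trough_d21=trough,
        predicted_cmax_at_proposed=float(cmax), actual_dose=actual_dose,
        percent_change=(percent_change(actual_dose, final)
                        if actual_dose else None),
        feasible=True, capped=capped,
        uncapped_dose=float(dose) if capped else None,
    )


def validation_report(patients: list[dict],
                      target: float = DEFAULT_TARGET_CMAX,
                      spacing_h: float = DEFAULT_SPACING_H
                      ) -> tuple[pd.DataFrame, dict]:
    """Course-2 individualization report for a validation cohort.

    Each patient dict carries ``patient_id``, a course-1 ``fit``
    (IndividualFit), the course-1 ``regimen``, the ``actual_dose`` given at
    course 2 and optionally ``measured_trough`` (ug/mL, drawn just before
    course 2), ``next_start`` (h, defaults to course-1 start + 21 days) and
    an ``outcome`` annotation.  Patients without course-2 data are excluded
    (logged in the summary).

    Returns the per-patient table and a summary with means +/- SD and the
    paired statistic t = mean(d) / (sd(d)/sqrt(n)) comparing simulated
    day-21 troughs with measured troughs.
    """
    rows, skipped = [], []
    for rec in patients:
        if rec.get("actual_dose") is None:
            skipped.append(rec.get("patient_id"))
            continue
        fit = rec["fit"]
        regimen = rec["regimen"]
        next_start = rec.get("next_start",
                             regimen[0].start + spacing_h)
        sim_trough = predict_trough(fit, regimen, next_start)
        prop = propose_dose(fit, regimen, next_start, target=target,
                            actual_dose=rec["actual_dose"], force=True)
        rows.append({
            "patient_id": rec.get("patient_id"),
            "predicted_trough_d21": sim_trough,
            "measured_trough": rec.get("measured_trough", np.nan),
            "actual_dose_mg": rec["actual_dose"],
            "proposed_dose_mg": prop.proposed_dose,
            "percent_change": prop.percent_change,
            "feasible": prop.feasible,
            "outcome": rec.get("outcome", ""),
        })
    table = pd.DataFrame(rows)

    summary = {"n": len(table), "excluded": skipped}
    if len(table):
        summary["proposed_dose_mean"] = float(table.proposed_dose_mg.mean())
        summary["proposed_dose_sd"] = float(table.proposed_dose_mg.std(ddof=1)) \
            if len(table) > 1 else 0.0
        summary["actual_dose_mean"] = float(table.actual_dose_mg.mean())
        paired = table.dropna(subset=["measured_trough"])
        if len(paired) > 1:
            d = (paired.predicted_trough_d21 - paired.measured_trough).values
            sd = float(np.std(d, ddof=1))
            summary["trough_diff_mean"] = float(np.mean(d))
            summary["trough_diff_sd"] = sd
            summary["paired_t"] = (float(np.mean(d) / (sd / math.sqrt(len(d))))
                                   if sd > 0 else 0.0)
    return table, summary
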