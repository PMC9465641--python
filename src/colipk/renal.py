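"""Urinary-recovery and renal-clearance analysis over a collection interval.

Renal clearance is estimated non-compartmentally as the amount of colistin
recovered in urine divided by the plasma AUC over the same interval
(linear trapezoid on the observed concentrations); urinary recovery is the
recovered amount as a percentage of the dose administered in the window,
and the renal fraction is CL_R over total body clearance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DoseEvent, PatientRecord, UrineInterval

logger = logging.getLogger(__name__)

__all__ = ["RenalSummary", "urinary_amount", "recovery_percent",
           "renal_clearance", "fraction_renal", "cumulative_excretion",
           "dose_in_window", "patient_renal_summary", "renal_report"]


@dataclass
class RenalSummary:
    """Per-patient urinary-excretion summary."""

    amount_excreted: float      # mg
    recovery_percent: float     # % of dose in window
    cl_renal: float             # L/h
    fraction_renal: float       # % of total CL
    cumulative_times: np.ndarray    # h (interval end points)
    cumulative_percent: np.ndarray  # % of dose, non-decreasing


def _check_non_overlapping(intervals: Sequence[UrineInterval]) -> list[UrineInterval]:
    ordered = sorted(intervals, key=lambda u: u.start_time)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_time < a.end_time - 1e-9:
            raise ValueError(
                f"overlapping urine intervals: [{a.start_time}, {a.end_time}] "
                f"and [{b.start_time}, {b.end_time}]")
    return ordered


def urinary_amount(intervals: Sequence[UrineInterval]) -> float:
    """Total colistin recovered (mg): sum of volume x concentration."""
    return sum(u.amount for u in _check_non_overlapping(intervals))


def recovery_percent(amount: float, dose_in_window: float) -> float:
    """Recovered amount as % of the dose administered in the window."""
    if dose_in_window <= 0:
        raise ValueError("dose in window must be positive")
    return 100.0 * amount / dose_in_window


def renal_clearance(amount: float, plasma_auc_same_interval: float) -> float:
    """CL_R (L/h) = amount excreted / plasma AUC over the same interval."""
    if plasma_auc_same_interval <= 0:
        raise ValueError("plasma AUC must be positive")
    return amount / plasma_auc_same_interval


def fraction_renal(cl_renal: float, cl_total: float) -> float:
    """Renal fraction of total clearance, %.  Values above 100% indicate
    inconsistent inputs and are returned with a warning."""
    if cl_total <= 0:
        raise ValueError("total clearance must be positive")
    frac = 100.0 * cl_renal / cl_total
    if frac > 100.0:
        logger.warning("renal fraction %.1f%% exceeds 100%%: inconsistent "
                       "CL_R (%.3g) vs CL (%.3g)", frac, cl_renal, cl_total)
    return frac


def cumulative_excretion(intervals: Sequence[UrineInterval],
                         dose_in_window: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative % of dose excreted at each collection end point."""
    ordered = _check_non_overlapping(intervals)
    times = np.array([u.end_time for u in ordered])
    cum = np.cumsum([u.amount for u in ordered])
    return times, 100.0 * cum / dose_in_window


def dose_in_window(doses: Sequence[DoseEvent], start: float, end: float,
                   default_interval: float = 12.0) -> float:
    """Dose (mg) attributed to a collection window.

    Each dose is prorated by the overlap of its dosing interval (from its
    start to the next dose, or ``default_interval`` for the last dose)
    with the window.
    """
    if end <= start:
        raise ValueError("window must have end > start")
    ordered = sorted(doses, key=lambda d: d.start_time)
    total = 0.0
    for i, d in enumerate(ordered):
        nxt = (ordered[i + 1].start_time if i + 1 < len(ordered)
               else d.start_time + default_interval)
        tau = max(nxt - d.start_time, 1e-9)
        overlap = max(0.0, min(end, nxt) - max(start, d.start_time))
        total += d.amount * overlap / tau
    return total


def _plasma_auc_trapezoid(record: PatientRecord, start: float,
                          end: float) -> float:
    """Linear-trapezoid AUC of observed plasma samples spanning [start, end].

    Requires observations bracketing the interval (within a 1.5-h margin);
    concentrations at the exact window edges are linearly interpolated.
    """
    samples = [(s.time, s.concentration) for s in record.quantifiable_plasma]
    if len(samples) < 2:
        raise ValueError(f"patient {record.patient_id}: need >= 2 plasma "
                         "samples for a trapezoid AUC")
    t = np.array([p[0] for p in samples])
    c = np.array([p[1] for p in samples])
    margin = 1.5
    if t.min() > start + margin or t.max() < end - margin:
        raise ValueError(
            f"patient {record.patient_id}: plasma sampling "
            f"[{t.min():.2f}, {t.max():.2f}] h does not cover the urine "
            f"interval [{start:.2f}, {end:.2f}] h")
    grid = np.unique(np.concatenate([[start, end], t[(t > start) & (t < end)]]))
    conc = np.interp(grid, t, c)
    return float(np.trapezoid(conc, grid))


def patient_renal_summary(record: PatientRecord, cl_total: float,
                          model_auc: float | None = None) -> RenalSummary:
    """Full renal summary for one patient with urine collections.

    ``cl_total`` is the patient's total clearance (e.g. the empirical-Bayes
    CL from the population fit).  The plasma AUC over the collection window
    is the observed-data trapezoid; pass ``model_auc`` to use a model-based
    AUC instead (sensitivity analysis).
    """
    if not record.urine:
        raise ValueError(f"patient {record.patient_id}: no urine collections")
    intervals = _check_non_overlapping(record.urine)
    start = intervals[0].start_time
    end = intervals[-1].end_time
    amount = urinary_amount(intervals)
    dose = dose_in_window(record.doses, start, end)
    auc = (model_auc if model_auc is not None
           else _plasma_auc_trapezoid(record, start, end))
    clr = renal_clearance(amount, auc)
    times, cum = cumulative_excretion(intervals, dose)
    return RenalSummary(
        amount_excreted=amount,
        recovery_percent=recovery_percent(amount, dose),
        cl_renal=clr,
        fraction_renal=fraction_renal(clr, cl_total),
        cumulative_times=times,
        cumulative_percent=cum,
    )


def renal_report(records: Sequence[PatientRecord],
                 cl_by_patient: dict[str, float]) -> pd.DataFrame:
    """One row per patient with urine data: amount, recovery %, CL_R,
    renal fraction %."""
    rows = []
    for r in records:
        if not r.urine:
            continue
        s = patient_renal_summary(r, cl_by_patient[r.patient_id])
        rows.append({"ID": r.patient_id, "AMOUNT_MG": s.amount_excreted,
                     "RECOVERY_PCT": s.recovery_percent,
                     "CLR_L_H": s.cl_renal,
                     "FRACTION_RENAL_PCT": s.fraction_renal})
    return pd.DataFrame(rows, columns=["ID", "AMOUNT_MG", "RECOVERY_PCT",
                                       "CLR_L_H", "FRACTION_RENAL_PCT"])
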