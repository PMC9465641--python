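"""Exposure-outcome correlation: ROC analysis of steady-state exposure
metrics (AUCss,0-24/MIC, Css,min, Css,max, Css,avg) against the binary
clinical outcome (valid/invalid).

The ROC curve and its area are computed with scikit-learn; AUC_ROC equals
the Mann-Whitney U statistic scaled by n1*n0 (ties counted 1/2), and group
comparisons between valid and invalid patients use the Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ExposureOutcomeRow", "roc_curve", "auc_roc", "roc_summary",
           "group_comparison"]

_METRICS = ("auc_mic_ratio", "css_min", "css_max", "css_avg")


@dataclass
class ExposureOutcomeRow:
    """One evaluable patient's exposure metrics and outcome label."""

    patient_id: str
    auc_mic_ratio: float | None   # h; None for empirical therapy (no MIC)
    css_min: float
    css_max: float
    css_avg: float
    outcome: str                  # "valid" | "invalid"

    def __post_init__(self) -> None:
        if self.outcome not in ("valid", "invalid"):
            raise ValueError("outcome must be 'valid' or 'invalid'")
        for name in _METRICS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC analysis requires both outcome classes")
    return labels


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points over all distinct thresholds, descending scores.

    ``labels``: 1 for the positive (valid) class, 0 otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr


def auc_roc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) over
    all (positive, negative) pairs (the Mann-Whitney statistic / n1*n0).
    """
    fpr, tpr = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def roc_summary(rows: Sequence[ExposureOutcomeRow]) -> pd.DataFrame:
    """AUC_ROC (with Mann-Whitney p-value) for each exposure metric.

    Patients without a causative-pathogen MIC are excluded from the
    AUC/MIC metric only.
    """
    out = []
    for metric in _METRICS:
        usable = [r for r in rows if getattr(r, metric) is not None]
        labels = np.array([1 if r.outcome == "valid" else 0 for r in usable])
        scores = np.array([getattr(r, metric) for r in usable], dtype=float)
        if len(np.unique(labels)) < 2:
            out.append({"metric": metric, "n": len(usable),
                        "auc_roc": np.nan, "p_value": np.nan})
            continue
        auc = auc_roc(scores, labels)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                               alternative="two-sided")
        out.append({"metric": metric, "n": len(usable), "auc_roc": auc,
                    "p_value": float(u.pvalue)})
    return pd.DataFrame(out)


def group_comparison(rows: Sequence[ExposureOutcomeRow],
                     metric: str = "auc_mic_ratio") -> dict:
    """Valid vs invalid group means of one metric with a Mann-Whitney test."""
    usable = [r for r in rows if getattr(r, metric) is not None]
    valid = np.array([getattr(r, metric) for r in usable
                      if r.outcome == "valid"], dtype=float)
    invalid = np.array([getattr(r, metric) for r in usable
                        if r.outcome == "invalid"], dtype=float)
    if len(valid) == 0 or len(invalid) == 0:
        raise ValueError("both outcome groups must be non-empty")
    u = stats.mannwhitneyu(valid, invalid, alternative="two-sided")
    return {"metric": metric,
            "mean_valid": float(valid.mean()),
            "mean_invalid": float(invalid.mean()),
            "n_valid": len(valid), "n_invalid": len(invalid),
            "p_value": float(u.pvalue)}


def read_rows(path) -> list[ExposureOutcomeRow]:
    """Read ExposureOutcomeRow records from CSV (columns ID, AUC_MIC,
    CSS_MIN, CSS_MAX, CSS_AVG, OUTCOME; AUC_MIC may be empty)."""
    frame = pd.read_csv(path, dtype={"ID": str})
    rows = []
    for _, r in frame.iterrows():
        amr = r.get("AUC_MIC")
        rows.append(ExposureOutcomeRow(
            patient_id=str(r["ID"]),
            auc_mic_ratio=None if pd.isna(amr) else float(amr),
            css_min=float(r["CSS_MIN"]), css_max=float(r["CSS_MAX"]),
            css_avg=float(r["CSS_AVG"]), outcome=str(r["OUTCOME"])))
    return rows


def write_rows(rows: Sequence[ExposureOutcomeRow], path) -> None:
    pd.DataFrame([{
        "ID": r.patient_id,
        "AUC_MIC": "" if r.auc_mic_ratio is None else r.auc_mic_ratio,
        "CSS_MIN": r.css_min, "CSS_MAX": r.css_max, "CSS_AVG": r.css_avg,
        "OUTCOME": r.outcome} for r in rows]).to_csv(path, index=False)
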