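"""Domain types, dataset I/O and unit conversions shared by all analysis stages.

Colistin sulfate is dosed in million units (MU); 10,000 IU of colistin
sulfate corresponds to 0.44 mg of colistin base activity, i.e. 44 mg per MU.
All internal amounts are mg, all times are hours since the patient's first
dose, all concentrations are mg/L of total colistin (colistin A + B).

The on-disk event-dataset dialect is a NONMEM-compatible CSV: one row per
dose (EVID=1) or observation (EVID=0), with per-patient covariate columns
repeated on every row.  See :func:`read_dataset` / :func:`write_dataset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: mg of colistin base activity per million units of colistin sulfate.
MG_PER_MU = 44.0

#: Lower limits of quantification of the plasma assay (mg/L).
LLOQ_COLISTIN_A = 0.034
LLOQ_COLISTIN_B = 0.059
#: LLOQ applied to the summed (total colistin) concentration.
LLOQ_TOTAL = LLOQ_COLISTIN_A + LLOQ_COLISTIN_B

SAMPLE_CLASSES = ("trough", "peak", "random")

#: Optional per-patient laboratory covariates accepted in ``Covariates.extras``.
EXTRA_COVARIATES = (
    "AST", "TBIL", "DBIL", "TBA", "TP", "ALB", "UA", "BUN", "WBC", "NEUT",
    "HGB", "RBC", "HCT", "PLT", "PT", "TT", "APTT", "PA", "FIB", "CRP",
    "PCT", "LAC", "UV24",
)


class DatasetError(ValueError):
    """Raised for malformed event datasets; message carries line numbers."""


def mu_to_mg(dose_mu: float) -> float:
    """Convert a colistin sulfate dose from million units to mg.

    Parameters
    ----------
    dose_mu : float
        Dose in million units (MU); must be non-negative.
    """
    if dose_mu < 0:
        raise ValueError(f"dose must be non-negative, got {dose_mu} MU")
    return dose_mu * MG_PER_MU


def cockcroft_gault(age: float, weight: float, serum_creatinine: float,
                    sex: str) -> float:
    """Creatinine clearance (ml/min) by the Cockcroft-Gault equation.

    CrCL = (140 - age) * weight / (72 * SCr), multiplied by 0.85 for females,
    with age in years, weight in kg and serum creatinine in mg/dL.
    """
    if serum_creatinine <= 0:
        raise ValueError("serum creatinine must be positive")
    if age <= 0 or age >= 140:
        raise ValueError("age must lie in (0, 140) years")
    if weight <= 0:
        raise ValueError("weight must be positive")
    crcl = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if _norm_sex(sex) == "female":
        crcl *= 0.85
    return crcl


def total_colistin(conc_a: float, conc_b: float) -> float:
    """Total colistin concentration: colistin A + colistin B (mg/L)."""
    if conc_a < 0 or conc_b < 0:
        raise ValueError("concentrations must be non-negative")
    return conc_a + conc_b


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("m", "male", "1"):
        return "male"
    if s in ("f", "female", "0"):
        return "female"
    raise ValueError(f"unrecognized sex: {sex!r}")


@dataclass
class DoseEvent:
    """A single zero-order intravenous infusion."""

    start_time: float      # h since first dose
    amount: float          # mg
    infusion_duration: float  # h

    def __post_init__(self) -> None:
        self.start_time = float(self.start_time)
        self.amount = float(self.amount)
        self.infusion_duration = float(self.infusion_duration)
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.infusion_duration <= 0:
            raise ValueError("infusion duration must be positive")
        if self.start_time < 0:
            raise ValueError("dose start time must be non-negative")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.infusion_duration


@dataclass
class PlasmaSample:
    """One observed total-colistin plasma concentration."""

    time: float            # h since first dose
    concentration: float   # mg/L
    sample_class: str = "random"
    below_lloq: bool = False

    def __post_init__(self) -> None:
        self.time = float(self.time)
        self.concentration = float(self.concentration)
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.sample_class not in SAMPLE_CLASSES:
            raise ValueError(f"sample_class must be one of {SAMPLE_CLASSES}")


@dataclass
class UrineInterval:
    """A timed urine collection over one interval."""

    start_time: float  # h
    end_time: float    # h
    volume: float      # L
    concentration: float  # mg/L

    def __post_init__(self) -> None:
        self.start_time = float(self.start_time)
        self.end_time = float(self.end_time)
        self.volume = float(self.volume)
        self.concentration = float(self.concentration)
        if self.end_time <= self.start_time:
            raise ValueError("urine interval must have end_time > start_time")
        if self.volume < 0 or self.concentration < 0:
            raise ValueError("urine volume and concentration must be >= 0")

    @property
    def amount(self) -> float:
        """Amount of colistin in the collection, mg."""
        return self.volume * self.concentration


@dataclass
class Covariates:
    """Per-patient covariates. ``crcl`` and ``alt`` are mandatory;
    the remaining candidate laboratory values live in ``extras``."""

    crcl: float    # ml/min
    alt: float     # U/L
    weight: float  # kg
    age: float     # years
    sex: str       # "male" | "female"
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.crcl = float(self.crcl)
        self.alt = float(self.alt)
        self.weight = float(self.weight)
        self.age = float(self.age)
        self.extras = {k: float(v) for k, v in self.extras.items()}
        if self.crcl <= 0 or self.alt <= 0 or self.weight <= 0:
            raise ValueError("crcl, alt and weight must be positive")
        if self.age < 18:
            raise ValueError("adult cohort: age must be >= 18")
        self.sex = _norm_sex(self.sex)

    def value(self, name: str) -> float:
        """Look up a covariate by its dataset column name (e.g. 'CRCL')."""
        key = name.upper()
        builtin = {"CRCL": self.crcl, "ALT": self.alt, "WT": self.weight,
                   "AGE": self.age, "SEX": 1.0 if self.sex == "female" else 0.0}
        if key in builtin:
            return builtin[key]
        if key in self.extras:
            return self.extras[key]
        raise KeyError(f"covariate {name!r} not present")


@dataclass
class PatientRecord:
    """All events and annotations for one patient."""

    patient_id: str
    covariates: Covariates
    doses: list[DoseEvent]
    plasma: list[PlasmaSample]
    urine: list[UrineInterval] = field(default_factory=list)
    outcome_label: str | None = None  # "valid" | "invalid" | None

    def __post_init__(self) -> None:
        if not self.doses:
            raise ValueError(f"patient {self.patient_id}: at least one dose required")
        times = [s.time for s in self.plasma]
        if any(t < 0 for t in times):
            raise ValueError(f"patient {self.patient_id}: sample before first dose")
        if any(b > a for a, b in zip(times[1:], times)):
            raise ValueError(f"patient {self.patient_id}: sample times must be non-decreasing")
        if self.outcome_label not in (None, "valid", "invalid"):
            raise ValueError("outcome_label must be 'valid', 'invalid' or None")

    @property
    def quantifiable_plasma(self) -> list[PlasmaSample]:
        """Samples usable for fitting (above the LLOQ)."""
        return [s for s in self.plasma if not s.below_lloq]


@dataclass
class Regimen:
    """A simulated dosing regimen, expressed in million units."""

    maintenance_dose: float       # MU per administration
    interval: int                 # h, 8 or 12
    loading_dose: float | None = None  # MU, given at t=0 if present
    infusion_duration: float = 2.0     # h

    def __post_init__(self) -> None:
        if self.maintenance_dose <= 0:
            raise ValueError("maintenance dose must be positive")
        if self.interval not in (8, 12):
            raise ValueError("dosing interval must be 8 or 12 h")
        if self.infusion_duration <= 0:
            raise ValueError("infusion duration must be positive")
        if self.loading_dose is not None and self.loading_dose <= 0:
            raise ValueError("loading dose, when present, must be positive")

    @property
    def daily_dose_mu(self) -> float:
        """Maintenance dose per 24 h, MU."""
        return self.maintenance_dose * 24.0 / self.interval

    @property
    def label(self) -> str:
        maint = f"{self.maintenance_dose:g}MU q{self.interval}h"
        if self.loading_dose is None:
            return maint
        return f"{self.loading_dose:g}MU + {maint}"

    def dose_events(self, duration: float) -> list[DoseEvent]:
        """Expand the regimen into infusion events covering [0, duration) h.

        A loading dose (if any) is given at t=0 and the first maintenance
        dose one interval later; without a loading dose maintenance starts
        at t=0.
        """
        events: list[DoseEvent] = []
        if self.loading_dose is not None:
            events.append(DoseEvent(0.0, mu_to_mg(self.loading_dose),
                                    self.infusion_duration))
            start = float(self.interval)
        else:
            start = 0.0
        t = start
        while t < duration:
            events.append(DoseEvent(t, mu_to_mg(self.maintenance_dose),
                                    self.infusion_duration))
            t += self.interval
        return events


# ---------------------------------------------------------------------------
# Event-dataset I/O (NONMEM-compatible CSV dialect)
# ---------------------------------------------------------------------------

_CORE_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV",
                 "CRCL", "ALT", "WT", "AGE", "SEX", "SCLASS", "BLQ", "OUTCOME"]


def write_dataset(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write patient records as a NONMEM-compatible event CSV.

    Columns: ID, TIME (h), AMT (mg), RATE (mg/h), EVID (1 dose /
    0 observation), DV (mg/L), MDV, covariates (CRCL, ALT, WT, AGE, SEX,
    extras), SCLASS, BLQ, OUTCOME.  Covariate values repeat on every row.
    """
    extra_names = sorted({k for r in records for k in r.covariates.extras})
    rows = []
    for rec in records:
        cov = rec.covariates
        base = {
            "ID": rec.patient_id,
            "CRCL": cov.crcl, "ALT": cov.alt, "WT": cov.weight,
            "AGE": cov.age, "SEX": 0 if cov.sex == "male" else 1,
            "OUTCOME": rec.outcome_label or "",
        }
        for name in extra_names:
            base[name] = cov.extras.get(name, "")
        events: list[dict] = []
        for d in rec.doses:
            events.append({**base, "TIME": d.start_time, "AMT": d.amount,
                           "RATE": d.rate, "EVID": 1, "DV": "", "MDV": 1,
                           "SCLASS": "", "BLQ": ""})
        for s in rec.plasma:
            events.append({**base, "TIME": s.time, "AMT": "", "RATE": "",
                           "EVID": 0, "DV": s.concentration, "MDV": 0,
                           "SCLASS": s.sample_class, "BLQ": int(s.below_lloq)})
        # doses before observations at identical times
        events.sort(key=lambda e: (e["TIME"], -e["EVID"]))
        rows.extend(events)
    frame = pd.DataFrame(rows, columns=_CORE_COLUMNS + extra_names)
    frame.to_csv(path, index=False)


def read_dataset(path: str | Path, lloq: float = LLOQ_TOTAL,
                 urine_path: str | Path | None = None) -> list[PatientRecord]:
    """Read a NONMEM-compatible event CSV into :class:`PatientRecord` objects.

    Observations with DV below ``lloq`` are flagged ``below_lloq`` (they are
    retained in the record but excluded from fitting).  Malformed rows are
    reported with 1-based file line numbers.  ``urine_path``, when given,
    merges urine-collection intervals (columns ID, TSTART, TEND, VOLUME_L,
    CONC_MGL) into the records.
    """
    frame = pd.read_csv(path, dtype={"ID": str})
    missing = [c for c in ("ID", "TIME", "EVID") if c not in frame.columns]
    if missing:
        raise DatasetError(f"{path}: missing required columns {missing}")
    extra_names = [c for c in frame.columns if c in EXTRA_COVARIATES]

    urine_by_id: dict[str, list[UrineInterval]] = {}
    if urine_path is not None:
        uf = pd.read_csv(urine_path, dtype={"ID": str})
        for _, row in uf.iterrows():
            urine_by_id.setdefault(str(row["ID"]), []).append(
                UrineInterval(float(row["TSTART"]), float(row["TEND"]),
                              float(row["VOLUME_L"]), float(row["CONC_MGL"])))

    records: list[PatientRecord] = []
    for pid, group in frame.groupby("ID", sort=False):
        doses: list[DoseEvent] = []
        plasma: list[PlasmaSample] = []
        for idx, row in group.iterrows():
            line = idx + 2  # header + 1-based
            evid = int(row["EVID"])
            if evid == 1:
                if not pd.isna(row.get("DV")) and str(row.get("DV")) != "":
                    raise DatasetError(
                        f"line {line}: DV recorded on an EVID=1 dosing row")
                amt = float(row["AMT"])
                rate = float(row["RATE"])
                if rate <= 0:
                    raise DatasetError(f"line {line}: dosing row needs RATE > 0")
                doses.append(DoseEvent(float(row["TIME"]), amt, amt / rate))
            elif evid == 0:
                if int(row.get("MDV", 0)) == 1:
                    continue
                dv = row.get("DV")
                if pd.isna(dv):
                    raise DatasetError(f"line {line}: observation row without DV")
                conc = float(dv)
                sclass = str(row.get("SCLASS", "random") or "random")
                if sclass not in SAMPLE_CLASSES:
                    sclass = "random"
                plasma.append(PlasmaSample(float(row["TIME"]), conc,
                                           sclass, conc < lloq))
            else:
                raise DatasetError(f"line {line}: unsupported EVID {evid}")
        if not doses:
            raise DatasetError(f"patient {pid}: no dosing records")
        first_dose = min(d.start_time for d in doses)
        early = [s for s in plasma if s.time < first_dose]
        if early:
            raise DatasetError(
                f"patient {pid}: {len(early)} observation(s) before first dose")
        plasma.sort(key=lambda s: s.time)
        head = group.iloc[0]
        for col in ("CRCL", "ALT", "WT", "AGE", "SEX"):
            if col not in group.columns:
                raise DatasetError(f"{path}: missing covariate column {col}")
            if group[col].nunique() > 1:
                raise DatasetError(
                    f"patient {pid}: covariate {col} varies within patient "
                    "(time-varying covariates are not supported)")
        extras = {}
        for name in extra_names:
            val = head[name]
            if pd.isna(val) or str(val) == "":
                logger.warning("patient %s: covariate %s missing; excluded "
                               "from covariate screening for this run", pid, name)
            else:
                extras[name] = float(val)
        outcome = head.get("OUTCOME")
        outcome = None if (outcome is None or pd.isna(outcome) or
                           str(outcome) == "") else str(outcome)
        cov = Covariates(crcl=float(head["CRCL"]), alt=float(head["ALT"]),
                         weight=float(head["WT"]), age=float(head["AGE"]),
                         sex="female" if int(head["SEX"]) == 1 else "male",
                         extras=extras)
        n_blq = sum(s.below_lloq for s in plasma)
        if n_blq:
            logger.warning("patient %s: %d sample(s) below LLOQ (%g mg/L) "
                           "flagged and excluded from fitting", pid, n_blq, lloq)
        records.append(PatientRecord(str(pid), cov, doses, plasma,
                                     urine_by_id.get(str(pid), []), outcome))
    return records


def write_urine(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write urine-collection intervals as CSV (ID, TSTART, TEND, VOLUME_L, CONC_MGL)."""
    rows = [{"ID": r.patient_id, "TSTART": u.start_time, "TEND": u.end_time,
             "VOLUME_L": u.volume, "CONC_MGL": u.concentration}
            for r in records for u in r.urine]
    pd.DataFrame(rows, columns=["ID", "TSTART", "TEND", "VOLUME_L",
                                "CONC_MGL"]).to_csv(path, index=False)
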