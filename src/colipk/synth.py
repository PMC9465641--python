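"""Virtual-study generator emulating the colistin sulfate cohort design.

Generates patient records with the statistical structure of the observed
study: ~20 critically ill adults, creatinine clearance spanning 6.5-193.8
ml/min, ALT 7-495 U/L, weight 45-65 kg, daily doses of 1.0-2.0 MU given as
2-3 infusions of 1-2 h, a plasma-sampling mix of troughs, peaks and random
draws collected after 72 h of therapy, and a 12-h timed urine collection in
a 6-patient subset.  The generating ("true") population parameters default
to the final-model estimates, so fitted models can be checked against a
known truth.

Continuous covariates are drawn *split log-uniformly*: with probability 1/2
log-uniform between the lower bound and the target median, otherwise
log-uniform between the median and the upper bound.  This pins the sample
median at the cohort's reported median while covering the full observed
range of these strongly right-skewed laboratory values.

An enriched-design generator (:func:`generate_enriched_study`) produces the
parameter-recovery protocol: many patients on a fixed 0.75 MU q12h regimen
with 8 samples across one late dosing interval, covariates log-uniform over
the cohort ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import (LLOQ_TOTAL, Covariates, DoseEvent, PatientRecord,
                   PlasmaSample, Regimen, UrineInterval, mu_to_mg)
from .pkmodel import (IndividualParams, PopulationParams, individual_params,
                      model_auc, simulate_profile)

__all__ = ["StudyDesign", "StudyTruth", "generate_true_params",
           "generate_study", "generate_enriched_study"]

_MIN5 = 5.0 / 60.0  # sampling jitter: 5 minutes, in hours


def generate_true_params() -> PopulationParams:
    """Final-model population estimates, used as the default simulation truth."""
    return PopulationParams(
        tvV=16.1, tvV2=50.5, tvCL=1.50, tvCL2=1.71,
        dV2dALT=0.635, dCLdCrCL=0.353,
        omega2_V=0.0267, omega2_CL=0.197, sigma_prop=0.228,
        crcl_ref=57.5, alt_ref=37.0,
    )


@dataclass
class StudyDesign:
    """Design of a virtual study mirroring the observed cohort."""

    n_patients: int = 20
    crcl_range: tuple[float, float] = (6.5, 193.8)   # ml/min
    crcl_median: float | None = 48.8
    alt_range: tuple[float, float] = (7.0, 495.0)    # U/L
    alt_median: float | None = 37.5
    weight_range: tuple[float, float] = (45.0, 65.0)  # kg
    age_range: tuple[float, float] = (18.0, 92.0)     # years
    female_fraction: float = 0.4
    #: daily maintenance dose (MU) -> probability
    daily_dose_mix: dict[float, float] = field(
        default_factory=lambda: {1.0: 0.10, 1.5: 0.70, 2.0: 0.20})
    loading_fraction: float = 0.2     # patients starting with a 1.0 MU load
    #: (trough, peak, random) sampling probabilities; the cohort's 38/27/33
    sampling_mix: tuple[float, float, float] = (38 / 98, 27 / 98, 33 / 98)
    n_rich_patients: int = 6          # patients with within-interval sampling
    n_samples_rich: int = 7
    n_samples_sparse: int = 4
    urine_subset_size: int = 6
    #: CL_R / CL drawn log-uniformly over this range (urinary recovery ~2-32%)
    urine_recovery_range: tuple[float, float] = (0.02, 0.32)
    therapy_duration: float = 96.0    # h of dosing simulated
    sampling_window: tuple[float, float] = (72.0, 96.0)  # h, after 72 h of therapy
    urine_interval: tuple[float, float] = (72.0, 84.0)   # one 12-h interval
    lloq: float = LLOQ_TOTAL
    true_params: PopulationParams = field(default_factory=generate_true_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.sampling_mix) - 1.0) > 1e-9:
            raise ValueError("sampling_mix must sum to 1")
        if abs(sum(self.daily_dose_mix.values()) - 1.0) > 1e-9:
            raise ValueError("daily_dose_mix must sum to 1")
        for lo, hi in (self.crcl_range, self.alt_range, self.weight_range,
                       self.age_range):
            if not (0 < lo < hi):
                raise ValueError("covariate ranges must be positive and ordered")
        if self.n_patients < 1 or self.urine_subset_size > self.n_patients:
            raise ValueError("infeasible patient counts")
        if self.n_rich_patients > self.n_patients:
            raise ValueError("rich-sampling subset larger than cohort")


@dataclass
class StudyTruth:
    """Hidden ground truth returned alongside a generated study."""

    params: PopulationParams
    eta: dict[str, tuple[float, float]]          # patient -> (eta_V, eta_CL)
    individual: dict[str, IndividualParams]
    cl_renal: dict[str, float]                   # L/h, urine subset only
    mic: dict[str, float]                        # mg/L, evaluable patients


def _split_loguniform(rng: np.random.Generator, lo: float, hi: float,
                      median: float | None, size: int) -> np.ndarray:
    """Log-uniform draw; if ``median`` is given, draw each half of the
    probability mass log-uniformly on either side of it."""
    if median is None:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))
    below = rng.random(size) < 0.5
    lo_draw = np.exp(rng.uniform(np.log(lo), np.log(median), size))
    hi_draw = np.exp(rng.uniform(np.log(median), np.log(hi), size))
    return np.where(below, lo_draw, hi_draw)


def _draw_covariates(design: StudyDesign, rng: np.random.Generator,
                     n: int) -> list[Covariates]:
    crcl = _split_loguniform(rng, *design.crcl_range, design.crcl_median, n)
    alt = _split_loguniform(rng, *design.alt_range, design.alt_median, n)
    wt = rng.uniform(*design.weight_range, n)
    age = rng.uniform(*design.age_range, n)
    female = rng.random(n) < design.female_fraction
    return [Covariates(crcl=float(crcl[i]), alt=float(alt[i]),
                       weight=float(wt[i]), age=float(age[i]),
                       sex="female" if female[i] else "male")
            for i in range(n)]


def _sample_times(rng: np.random.Generator, doses: Sequence[DoseEvent],
                  window: tuple[float, float], n: int,
                  mix: tuple[float, float, float]) -> list[tuple[float, str]]:
    """Draw (time, class) pairs: troughs 5 min pre-dose, peaks 5 min after
    the end of an infusion, random samples uniform over the window."""
    lo, hi = window
    trough_t = [d.start_time - _MIN5 for d in doses
                if lo <= d.start_time - _MIN5 <= hi]
    peak_t = [d.start_time + d.infusion_duration + _MIN5 for d in doses
              if lo <= d.start_time + d.infusion_duration + _MIN5 <= hi]
    out: list[tuple[float, str]] = []
    for _ in range(n):
        cls = ("trough", "peak", "random")[rng.choice(3, p=mix)]
        if cls == "trough" and trough_t:
            t = float(trough_t[rng.integers(len(trough_t))])
        elif cls == "peak" and peak_t:
            t = float(peak_t[rng.integers(len(peak_t))])
        else:
            cls = "random"
            t = float(rng.uniform(lo, hi))
        out.append((t, cls))
    out.sort(key=lambda p: p[0])
    return out


def generate_study(design: StudyDesign) -> tuple[list[PatientRecord], StudyTruth]:
    """Generate one virtual study plus its hidden truth.

    Returns the patient records (dosing, noisy plasma samples, urine
    collections in the designated subset, probabilistic outcome labels) and
    a :class:`StudyTruth` carrying the per-patient random effects, realized
    structural parameters, true renal clearances and assigned MICs.
    """
    rng = np.random.default_rng(design.seed)
    p = design.true_params
    n = design.n_patients
    covs = _draw_covariates(design, rng, n)
    eta_v = rng.normal(0.0, np.sqrt(p.omega2_V), n)
    eta_cl = rng.normal(0.0, np.sqrt(p.omega2_CL), n)

    doses_mu = list(design.daily_dose_mix)
    probs = np.array([design.daily_dose_mix[d] for d in doses_mu])
    daily = rng.choice(doses_mu, size=n, p=probs)
    n_inf = rng.choice([2, 3], size=n)          # infusions per day
    inf_dur = rng.choice([1.0, 2.0], size=n)    # h
    loading = rng.random(n) < design.loading_fraction

    rich = set(rng.choice(n, size=design.n_rich_patients, replace=False))
    urine_ids = set(rng.choice(n, size=design.urine_subset_size, replace=False))

    records: list[PatientRecord] = []
    truth = StudyTruth(params=p, eta={}, individual={}, cl_renal={}, mic={})
    for i in range(n):
        pid = f"P{i + 1:03d}"
        interval = 12 if n_inf[i] == 2 else 8
        reg = Regimen(maintenance_dose=float(daily[i]) / float(n_inf[i]),
                      interval=interval,
                      loading_dose=1.0 if loading[i] else None,
                      infusion_duration=float(inf_dur[i]))
        doses = reg.dose_events(design.therapy_duration)
        ind = individual_params(p, covs[i], eta_v[i], eta_cl[i])

        n_samp = design.n_samples_rich if i in rich else design.n_samples_sparse
        if i in rich:
            # within-interval template over one late dosing interval:
            # pre-dose trough, mid-infusion, post-infusion peak, then the
            # distribution and elimination phases out to the next trough
            t0 = design.sampling_window[0]
            dur = reg.infusion_duration
            offs = [-_MIN5, dur / 2, dur + _MIN5, dur + 1.0, dur + 3.0,
                    interval / 2 + dur, interval - _MIN5]
            cls = ["trough", "random", "peak", "random", "random", "random",
                   "trough"]
            pairs = [(t0 + o, c) for o, c in zip(offs[:n_samp], cls[:n_samp])]
        else:
            pairs = _sample_times(rng, doses, design.sampling_window, n_samp,
                                  design.sampling_mix)
        times = np.array([t for t, _ in pairs])
        pred = simulate_profile(ind, doses, times).concentrations
        obs = np.clip(pred * (1.0 + rng.normal(0, p.sigma_prop, len(times))),
                      0.0, None)
        plasma = [PlasmaSample(float(t), float(c), cls, c < design.lloq)
                  for (t, cls), c in zip(pairs, obs)]

        urine: list[UrineInterval] = []
        if i in urine_ids:
            lo, hi = design.urine_recovery_range
            clr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))) * ind.CL)
            u0, u1 = design.urine_interval
            amount = clr * model_auc(ind, doses, u0, u1)
            volume = float(rng.uniform(0.5, 3.0))
            urine.append(UrineInterval(u0, u1, volume, amount / volume))
            truth.cl_renal[pid] = clr

        records.append(PatientRecord(pid, covs[i], doses, plasma, urine, None))
        truth.eta[pid] = (float(eta_v[i]), float(eta_cl[i]))
        truth.individual[pid] = ind

    # outcome labels for a 16-of-20-style evaluable subset: probability of a
    # valid outcome increases with fAUC/MIC through a logistic link
    n_eval = max(0, n - max(1, round(n * 0.2)))
    evaluable = rng.choice(n, size=n_eval, replace=False)
    for i in evaluable:
        pid = f"P{i + 1:03d}"
        mic = float(rng.choice([0.5, 1.0, 2.0], p=[0.5, 0.3, 0.2]))
        ind = truth.individual[pid]
        reg_daily = float(daily[i])
        fauc = 0.49 * mu_to_mg(reg_daily) / ind.CL  # steady-state daily fAUC
        logit = 1.5 * (np.log(fauc / mic) - np.log(20.0))
        valid = rng.random() < 1.0 / (1.0 + np.exp(-logit))
        records[i].outcome_label = "valid" if valid else "invalid"
        truth.mic[pid] = mic
    return records, truth


def generate_enriched_study(n_patients: int = 200,
                            params: PopulationParams | None = None,
                            seed: int = 0,
                            n_samples: int = 8
                            ) -> tuple[list[PatientRecord], StudyTruth]:
    """Parameter-recovery design: ``n_patients`` virtual patients on
    0.75 MU q12h (2-h infusions, 6 doses over 72 h) with ``n_samples``
    plasma samples across the final dosing interval, including early
    post-infusion times so the distribution phase is informative.
    Covariates are log-uniform over the cohort ranges.
    """
    p = params or generate_true_params()
    rng = np.random.default_rng(seed)
    design = StudyDesign()  # ranges only; medians overridden below
    reg = Regimen(maintenance_dose=0.75, interval=12, infusion_duration=2.0)
    doses = reg.dose_events(72.0)
    # offsets into the [60, 72] h interval: pre-dose trough, mid-infusion,
    # end-of-infusion peak, distribution phase, elimination, next trough
    offs = np.array([-_MIN5, 1.0, 2.0 + _MIN5, 2.5, 3.5, 5.0, 8.0,
                     12.0 - _MIN5])[:n_samples]
    classes = ["trough", "random", "peak", "random", "random", "random",
               "random", "trough"][:n_samples]
    times = 60.0 + offs

    crcl = _split_loguniform(rng, *design.crcl_range, None, n_patients)
    alt = _split_loguniform(rng, *design.alt_range, None, n_patients)
    wt = rng.uniform(*design.weight_range, n_patients)
    age = rng.uniform(*design.age_range, n_patients)
    female = rng.random(n_patients) < design.female_fraction
    eta_v = rng.normal(0.0, np.sqrt(p.omega2_V), n_patients)
    eta_cl = rng.normal(0.0, np.sqrt(p.omega2_CL), n_patients)

    records: list[PatientRecord] = []
    truth = StudyTruth(params=p, eta={}, individual={}, cl_renal={}, mic={})
    for i in range(n_patients):
        pid = f"S{i + 1:04d}"
        cov = Covariates(crcl=float(crcl[i]), alt=float(alt[i]),
                         weight=float(wt[i]), age=float(age[i]),
                         sex="female" if female[i] else "male")
        ind = individual_params(p, cov, eta_v[i], eta_cl[i])
        pred = simulate_profile(ind, doses, times).concentrations
        obs = np.clip(pred * (1.0 + rng.normal(0, p.sigma_prop, len(times))),
                      0.0, None)
        plasma = [PlasmaSample(float(t), float(c), cls, c < LLOQ_TOTAL)
                  for t, c, cls in zip(times, obs, classes)]
        records.append(PatientRecord(pid, cov, list(doses), plasma))
        truth.eta[pid] = (float(eta_v[i]), float(eta_cl[i]))
        truth.individual[pid] = ind
    return records, truth
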