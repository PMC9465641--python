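"""Structural two-compartment IV-infusion model with covariate equations.

The disposition model is linear and two-compartmental: central volume V,
peripheral volume V2, elimination clearance CL and inter-compartmental
clearance CL2.  Concentrations are evaluated in closed form through the
macro-exponential constants

    alpha + beta = k10 + k12 + k21,   alpha * beta = k10 * k21,

with k10 = CL/V, k12 = CL2/V, k21 = CL2/V2, superposing zero-order
infusion inputs.  The final covariate model ties CL to creatinine
clearance and V2 to ALT through power functions normalised at the
reference covariate values:

    V   = tvV * exp(eta_V)
    V2  = tvV2 * (ALT / alt_ref)^dV2dALT
    CL  = tvCL * (CrCL / crcl_ref)^dCLdCrCL * exp(eta_CL)
    CL2 = tvCL2

Inter-individual variability is log-normal on V and CL; V2 and CL2 carry
none.  Residual variability is proportional.

All closed forms are written with divided differences of exponentials so
that they stay accurate when the two disposition rate constants approach
each other (repeated-root limit) and when one of them approaches zero
(one-compartment limit).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data import Covariates, DoseEvent, Regimen

__all__ = [
    "PopulationParams", "IndividualParams", "ConcentrationProfile",
    "ExposureMetrics", "individual_params", "simulate_profile", "model_auc",
    "exposure_metrics", "steady_state_css_avg", "add_residual_error",
]


@dataclass
class PopulationParams:
    """Population (typical) parameters of the final covariate model."""

    tvV: float          # L
    tvV2: float         # L
    tvCL: float         # L/h
    tvCL2: float        # L/h
    dV2dALT: float      # power of (ALT/alt_ref) on V2
    dCLdCrCL: float     # power of (CrCL/crcl_ref) on CL
    omega2_V: float     # variance of log-scale eta_V
    omega2_CL: float    # variance of log-scale eta_CL
    sigma_prop: float   # proportional residual SD
    crcl_ref: float = 57.5  # ml/min
    alt_ref: float = 37.0   # U/L

    def __post_init__(self) -> None:
        for name in ("tvV", "tvV2", "tvCL", "tvCL2", "sigma_prop",
                     "crcl_ref", "alt_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.omega2_V < 0 or self.omega2_CL < 0:
            raise ValueError("IIV variances must be non-negative")

    def replace(self, **kw) -> "PopulationParams":
        return replace(self, **kw)


@dataclass
class IndividualParams:
    """Realized structural parameters for one subject."""

    V: float    # L
    V2: float   # L
    CL: float   # L/h
    CL2: float  # L/h

    def __post_init__(self) -> None:
        if min(self.V, self.V2, self.CL) <= 0 or self.CL2 < 0:
            raise ValueError("V, V2, CL must be positive and CL2 >= 0")


@dataclass
class ConcentrationProfile:
    times: np.ndarray           # h
    concentrations: np.ndarray  # mg/L

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must align")

    def to_frame(self, patient_id: str = ""):
        """Tidy export (ID, TIME, CONC) for CSV writing."""
        import pandas as pd
        return pd.DataFrame({"ID": patient_id, "TIME": self.times,
                             "CONC": self.concentrations})


@dataclass
class ExposureMetrics:
    """Exposure summaries used by the dosing simulations and outcome analysis."""

    auc_0_24_day1: float  # mg*h/L over [0, 24] h
    auc_24_day3: float    # mg*h/L over [48, 72] h
    css_min: float        # mg/L, pre-dose on the evaluated interval
    css_max: float        # mg/L, end of infusion on the evaluated interval
    css_avg: float        # mg/L, interval AUC / tau
    css_avg_ss: float = float("nan")  # mg/L, infinite-time limit: daily dose/(24 CL)


def individual_params(pop: PopulationParams, cov: Covariates,
                      eta_V: float = 0.0, eta_CL: float = 0.0) -> IndividualParams:
    """Realize one subject's structural parameters from the covariate model."""
    if cov.crcl <= 0 or cov.alt <= 0:
        raise ValueError("CrCL and ALT must be positive")
    return IndividualParams(
        V=pop.tvV * np.exp(eta_V),
        V2=pop.tvV2 * (cov.alt / pop.alt_ref) ** pop.dV2dALT,
        CL=pop.tvCL * (cov.crcl / pop.crcl_ref) ** pop.dCLdCrCL * np.exp(eta_CL),
        CL2=pop.tvCL2,
    )


# ---------------------------------------------------------------------------
# Closed-form kernels
# ---------------------------------------------------------------------------

def _em1(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x with the x -> 0 limit of 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x / 2.0, -np.expm1(-xs) / xs)


def _h2(z: np.ndarray) -> np.ndarray:
    """(z + exp(-z) - 1) / z**2 with the z -> 0 limit of 1/2."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-4
    zs = np.where(small, 1.0, z)
    return np.where(small, 0.5 - z / 6.0 + z * z / 24.0,
                    (zs + np.exp(-zs) - 1.0) / (zs * zs))


def _sinch(x: np.ndarray) -> np.ndarray:
    """sinh(x)/x with the x -> 0 limit of 1.

    The argument is clamped to +-60: this helper only feeds the
    near-repeated-root branch, whose values are discarded wherever
    |alpha - beta| * t is large.
    """
    x = np.clip(np.asarray(x, dtype=float), -60.0, 60.0)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 + x * x / 6.0, np.sinh(xs) / xs)


def _disposition(V, V2, CL, CL2):
    """Macro rate constants (alpha >= beta) and k21 from micro constants."""
    k10 = CL / V
    k12 = CL2 / V
    k21 = CL2 / np.maximum(V2, 1e-300)
    a = k10 + k12 + k21
    disc = np.sqrt(np.maximum(a * a - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (a + disc)
    beta = 0.5 * (a - disc)
    return alpha, beta, k21


def concentration(t, dose_t0, dose_T, dose_rate, V, V2, CL, CL2):
    """Central-compartment concentration at times ``t`` (vectorized).

    Parameters broadcast: ``t`` has shape (..., J), the dose arrays
    (..., K), the structural parameters (...,).  Doses with rate 0 act as
    padding and contribute nothing.  Returns shape (..., J).
    """
    with np.errstate(all="ignore"):
        return _concentration_impl(t, dose_t0, dose_T, dose_rate, V, V2, CL, CL2)


def _concentration_impl(t, dose_t0, dose_T, dose_rate, V, V2, CL, CL2):
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    alpha, beta, k21 = _disposition(V, V2, np.asarray(CL, float),
                                    np.asarray(CL2, float))
    # expand: times axis -2, doses axis -1
    tt = t[..., :, None]
    t0 = np.asarray(dose_t0, float)[..., None, :]
    T = np.asarray(dose_T, float)[..., None, :]
    R = np.asarray(dose_rate, float)[..., None, :]
    al = alpha[..., None, None]
    be = beta[..., None, None]
    k21e = k21[..., None, None]
    Ve = V[..., None, None]

    trel = tt - t0
    s = np.clip(np.minimum(trel, T), 0.0, None)   # time infused
    u = np.clip(trel - T, 0.0, None)               # time since infusion end
    te = s + u                                     # time since dose start (clipped)

    delta = al - be

    def phi(lam):
        # exp(-lam*u) * (1 - exp(-lam*s)) / lam, stable for lam*s -> 0
        return np.exp(-lam * u) * s * _em1(lam * s)

    active = trel > 0.0
    near = active & (delta * te < 1e-6)  # alpha ~ beta: divided differences
    delta_safe = np.where(delta * np.maximum(te, 1e-12) < 1e-6, 1.0, delta)
    A = (al - k21e) / delta_safe
    B = (k21e - be) / delta_safe
    contrib = A * phi(al) + B * phi(be)

    if near.any():
        lam_bar = 0.5 * (al + be)

        def ddg(tau):
            # (exp(-alpha*tau) - exp(-beta*tau)) / (alpha - beta)
            return -tau * np.exp(-lam_bar * tau) * _sinch(0.5 * delta * tau)

        d1 = ddg(u) - ddg(te)
        # phi'(lam_bar) where phi(lam) = int_u^te exp(-lam*tau) dtau
        z_t, z_u = lam_bar * te, lam_bar * u
        small_lam = np.maximum(z_t, z_u) < 1e-6
        lam_s = np.where(small_lam, 1.0, lam_bar)
        d2_series = -0.5 * (te * te - u * u)
        d2_exact = (np.exp(-lam_s * te) * (lam_s * te + 1.0)
                    - np.exp(-lam_s * u) * (lam_s * u + 1.0)) / (lam_s * lam_s)
        d2 = np.where(small_lam, d2_series, d2_exact)
        contrib = np.where(near, d1 - k21e * d2, contrib)

    return ((R / Ve) * np.where(active, contrib, 0.0)).sum(axis=-1)


def _cumint(lam, x, T):
    """int_0^x of exp(-lam*u(t)) * (1 - exp(-lam*s(t))) / lam dt for one dose."""
    xc = np.clip(np.minimum(x, T), 0.0, None)
    xr = np.clip(x - T, 0.0, None)
    return xc * xc * _h2(lam * xc) + xc * xr * _em1(lam * xc) * _em1(lam * xr)


def auc(t0, t1, dose_t0, dose_T, dose_rate, V, V2, CL, CL2):
    """Analytic AUC of the closed-form profile over [t0, t1] (vectorized).

    ``t0``/``t1`` broadcast against the parameter shape (...,); the dose
    arrays have shape (..., K).  Returns shape (...,).
    """
    V = np.asarray(V, dtype=float)
    alpha, beta, k21 = _disposition(V, V2, np.asarray(CL, float),
                                    np.asarray(CL2, float))
    delta = np.maximum(alpha - beta, (alpha + beta) * 1e-12)
    A = (alpha - k21) / delta
    B = (k21 - beta) / delta

    d0 = np.asarray(dose_t0, float)
    T = np.asarray(dose_T, float)
    R = np.asarray(dose_rate, float)
    al = alpha[..., None]
    be = beta[..., None]
    Ae = A[..., None]
    Be = B[..., None]
    Ve = V[..., None]

    def F(x):
        x = np.clip(np.asarray(x, float)[..., None] - d0, 0.0, None)
        return (R / Ve) * (Ae * _cumint(al, x, T) + Be * _cumint(be, x, T))

    return (F(t1) - F(t0)).sum(axis=-1)


def _dose_arrays(doses: Sequence[DoseEvent]):
    t0 = np.array([d.start_time for d in doses], dtype=float)
    T = np.array([d.infusion_duration for d in doses], dtype=float)
    R = np.array([d.rate for d in doses], dtype=float)
    return t0, T, R


def simulate_profile(ind: IndividualParams, doses: Sequence[DoseEvent],
                     times) -> ConcentrationProfile:
    """Closed-form concentration-time profile for one subject."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    t0, T, R = _dose_arrays(doses)
    conc = concentration(times, t0, T, R, ind.V, ind.V2, ind.CL, ind.CL2)
    return ConcentrationProfile(times, conc)


def model_auc(ind: IndividualParams, doses: Sequence[DoseEvent],
              t0: float, t1: float) -> float:
    """Analytic AUC (mg*h/L) of the model profile over [t0, t1].

    ``t1`` may be ``inf``; the [0, inf) integral of any dose set equals
    total dose / CL exactly (linear-model identity).
    """
    if not (t1 > t0 >= 0):
        raise ValueError("require t1 > t0 >= 0")
    d0, T, R = _dose_arrays(doses)
    if np.isinf(t1):
        total = float(np.sum(R * T))
        whole = total / ind.CL
        if t0 == 0:
            return whole
        return whole - model_auc(ind, doses, 0.0, t0)
    return float(auc(t0, t1, d0, T, R, ind.V, ind.V2, ind.CL, ind.CL2))


def steady_state_css_avg(CL: float, regimen: Regimen) -> float:
    """True steady-state average concentration: daily dose / (24 * CL), mg/L."""
    from .data import mu_to_mg
    return mu_to_mg(regimen.daily_dose_mu) / (24.0 * CL)


def exposure_metrics(ind: IndividualParams, regimen: Regimen,
                     eval_day: int = 3) -> ExposureMetrics:
    """Exposure metrics for a regimen, evaluated on the dosing interval that
    ends at 24 * eval_day hours (the day-3 interval for the default).

    Css,min is the pre-dose concentration at the start of that interval,
    Css,max the end-of-infusion concentration, and Css,avg the interval AUC
    divided by the interval length.
    """
    if eval_day < 1:
        raise ValueError("eval_day must be >= 1")
    horizon = max(72.0, 24.0 * eval_day)
    doses = regimen.dose_events(horizon)
    tau = float(regimen.interval)
    end = 24.0 * eval_day
    start = end - tau
    d0, T, R = _dose_arrays(doses)
    pars = (ind.V, ind.V2, ind.CL, ind.CL2)
    cmin, cmax = concentration(
        np.array([start, start + regimen.infusion_duration]), d0, T, R, *pars)
    interval_auc = float(auc(start, end, d0, T, R, *pars))
    return ExposureMetrics(
        auc_0_24_day1=float(auc(0.0, 24.0, d0, T, R, *pars)),
        auc_24_day3=float(auc(48.0, 72.0, d0, T, R, *pars)),
        css_min=float(cmin),
        css_max=float(cmax),
        css_avg=interval_auc / tau,
        css_avg_ss=steady_state_css_avg(ind.CL, regimen),
    )


def add_residual_error(conc, sigma_prop: float, rng: np.random.Generator):
    """Apply the proportional residual-error model: c * (1 + eps).

    Negative draws are truncated at zero; the truncation count is returned
    implicitly through a module logger message.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if sigma_prop < 0:
        raise ValueError("sigma_prop must be non-negative")
    if sigma_prop == 0:
        return conc.copy()
    eps = rng.normal(0.0, sigma_prop, size=conc.shape)
    obs = conc * (1.0 + eps)
    n_neg = int(np.sum(obs < 0))
    if n_neg:
        import logging
        logging.getLogger(__name__).warning(
            "%d simulated observation(s) truncated at 0", n_neg)
    return np.clip(obs, 0.0, None)
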