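"""Two-point first-order AUC estimators for a first IV-infusion dose.

Both estimators take exactly two post-infusion concentrations C1 (sampled
t1 after the end of the infusion) and C2 (sampled later, toward the end of
the dosing interval) and assume mono-exponential first-order decline between
and beyond them:

    Ke = ln(C1/C2) / (t2 - t1)

* Model 1 back-extrapolates to the end of infusion, C_eoi' = C1 e^{Ke t1},
  and takes the full AUC as a triangle over the infusion plus the
  exponential tail:  AUC_f = t_eoi * C_eoi'/2 + C_eoi'/Ke.
* Model 2 back-extrapolates all the way to the start of the infusion,
  C_0' = C1 e^{Ke (t1 + t_eoi)}, and integrates a single exponential from
  time zero:  AUC_f = C_0'/Ke.  The extra area (e^x > 1 + x) partially
  compensates for the unmeasured alpha-distribution phase, so Model 2 is
  strictly larger than Model 1 on any valid input.

Derived parameters follow the TDM conventions CL = dose/AUC_f,
Vd = CL/Ke, t1/2 = ln2/Ke.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .simcohort import ConcProfile, DoseRegimen

LN2 = math.log(2.0)

__all__ = [
    "TwoPointObs",
    "AucEstimate",
    "NonDecliningPair",
    "ke_two_point",
    "extrapolate_to_eoi",
    "extrapolate_to_t0",
    "auc_model1",
    "auc_model2",
    "derive_pk",
    "estimate",
    "two_point_from_profile",
    "MODELS",
]


class NonDecliningPair(ValueError):
    """C1 <= C2: the pair defines no positive elimination rate."""


@dataclass(frozen=True)
class TwoPointObs:
    """Two concentrations with times in hours after the END of the infusion."""

    t1_h: float
    c1: float
    t2_h: float
    c2: float
    regimen: DoseRegimen

    def __post_init__(self) -> None:
        if not 0 <= self.t1_h < self.t2_h:
            raise ValueError("require 0 <= t1 < t2")
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class AucEstimate:
    """An AUC estimate and the intermediates that produced it."""

    method: str  # "model1" | "model2"
    ke: float  # 1/h
    c_eoi_prime: float  # mg/L, back-extrapolated end-of-infusion conc
    auc_f: float  # mg*h/L
    c0_prime: float | None = None  # mg/L, start-of-infusion conc (model2)
    cl: float | None = None  # L/h
    vd: float | None = None  # L
    t_half: float | None = None  # h


def ke_two_point(obs: TwoPointObs) -> float:
    """Ke = ln(C1/C2)/(t2 - t1); requires a declining pair."""
    if obs.c1 <= obs.c2:
        raise NonDecliningPair(
            f"C1={obs.c1:.4g} <= C2={obs.c2:.4g}: no positive Ke"
        )
    return math.log(obs.c1 / obs.c2) / (obs.t2_h - obs.t1_h)


def extrapolate_to_eoi(obs: TwoPointObs, ke: float) -> float:
    """C_eoi' = C1 e^{Ke t1}: concentration at the end of the infusion."""
    if ke <= 0:
        raise ValueError("ke must be positive")
    return obs.c1 * math.exp(ke * obs.t1_h)


def extrapolate_to_t0(obs: TwoPointObs, ke: float) -> float:
    """C_0' = C1 e^{Ke (t1 + t_eoi)}: concentration at the start of infusion."""
    if ke <= 0:
        raise ValueError("ke must be positive")
    return obs.c1 * math.exp(ke * (obs.t1_h + obs.regimen.t_eoi_h))


def auc_model1(obs: TwoPointObs) -> AucEstimate:
    """Triangle over the infusion + exponential tail from the end of infusion."""
    ke = ke_two_point(obs)
    c_eoi = extrapolate_to_eoi(obs, ke)
    auc = obs.regimen.t_eoi_h * c_eoi / 2.0 + c_eoi / ke
    return AucEstimate(method="model1", ke=ke, c_eoi_prime=c_eoi, auc_f=auc)


def auc_model2(obs: TwoPointObs) -> AucEstimate:
    """Single exponential integrated from the start of infusion: C_0'/Ke."""
    ke = ke_two_point(obs)
    c_eoi = extrapolate_to_eoi(obs, ke)
    c0 = c_eoi * math.exp(ke * obs.regimen.t_eoi_h)
    return AucEstimate(
        method="model2", ke=ke, c_eoi_prime=c_eoi, c0_prime=c0, auc_f=c0 / ke
    )


def derive_pk(est: AucEstimate, regimen: DoseRegimen) -> AucEstimate:
    """Complete an estimate with CL = dose/AUC, Vd = CL/Ke, t1/2 = ln2/Ke."""
    if not est.auc_f > 0:
        raise ValueError("auc_f must be positive")
    cl = regimen.dose_mg / est.auc_f
    return replace(est, cl=cl, vd=cl / est.ke, t_half=LN2 / est.ke)


MODELS = {"model1": auc_model1, "model2": auc_model2}


def estimate(obs: TwoPointObs, method: str) -> AucEstimate:
    """Run one model and fill in the derived parameters."""
    try:
        fn = MODELS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(MODELS)}")
    return derive_pk(fn(obs), obs.regimen)


def two_point_from_profile(
    profile: ConcProfile, t1_min: float, t2_min: float
) -> TwoPointObs:
    """Pick C1/C2 out of a sampled profile by post-infusion offset (minutes)."""
    return TwoPointObs(
        t1_h=t1_min / 60.0,
        c1=profile.conc_at_offset_min(t1_min),
        t2_h=t2_min / 60.0,
        c2=profile.conc_at_offset_min(t2_min),
        regimen=profile.regimen,
    )
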