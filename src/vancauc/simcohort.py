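"""Synthetic intensive-sampling vancomycin cohorts.

Generates virtual subjects from a two-compartment IV-infusion model with
lognormal inter-individual variability and proportional (lognormal) assay
noise, emulating two first-dose study designs:

* an adult cohort (30 mg/kg infused over 120 min, samples at
  0, 10, 20, 40, 60, 90, 120 and 240 min after the end of the infusion), and
* a pediatric cohort (15 mg/kg over 60 min, samples at
  0, 15, 30, 60, 120, 180, 240 and 300 min after the end of the infusion).

All stored times are hours since the START of the infusion; sampling
schedules are specified as minutes after the END of the infusion (the
convention used in limited-sampling TDM work) and converted internally.
Each profile additionally carries a pre-dose zero sample and, for the adult
design, a mid-infusion sample, so profiles hold 10 (adult) / 9 (pediatric)
concentrations.

Every virtual subject's ground truth is kept alongside the noisy profile:
the micro-constants (CL, V1, V2, Q) and the analytic full AUC = dose/CL,
so estimator bias can be measured against the truth as well as against the
noncompartmental reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LN2 = math.log(2.0)

__all__ = [
    "DoseRegimen",
    "SubjectPK",
    "MacroConstants",
    "SamplingSchedule",
    "ConcProfile",
    "CohortSpec",
    "InfeasibleParameters",
    "adult_cohort_spec",
    "pediatric_cohort_spec",
    "sample_subject",
    "macro_constants",
    "conc_at",
    "simulate_profile",
    "generate_cohort",
    "dense_profile",
    "profiles_to_frame",
    "frame_to_profiles",
    "write_cohort",
    "read_profiles",
]


class InfeasibleParameters(ValueError):
    """No positive-real (V1, V2, Q) split exists for the requested kinetics."""


@dataclass(frozen=True)
class DoseRegimen:
    """A single constant-rate IV infusion starting at time 0."""

    dose_mg: float
    t_eoi_h: float  # infusion duration; "end of infusion" time

    def __post_init__(self) -> None:
        if not self.dose_mg > 0:
            raise ValueError(f"dose must be positive, got {self.dose_mg}")
        if not self.t_eoi_h > 0:
            raise ValueError(f"infusion duration must be positive, got {self.t_eoi_h}")


@dataclass(frozen=True)
class SubjectPK:
    """True two-compartment parameters of one virtual subject.

    CL: elimination clearance (L/h); V1/V2: central/peripheral volumes (L);
    Q: inter-compartmental clearance (L/h); weight in kg.
    """

    subject_id: str
    weight_kg: float
    cl: float
    v1: float
    v2: float
    q: float

    def __post_init__(self) -> None:
        for name in ("weight_kg", "cl", "v1", "v2", "q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def k10(self) -> float:
        return self.cl / self.v1

    @property
    def k12(self) -> float:
        return self.q / self.v1

    @property
    def k21(self) -> float:
        return self.q / self.v2

    @property
    def vss(self) -> float:
        return self.v1 + self.v2


@dataclass(frozen=True)
class MacroConstants:
    """Hybrid (macro) constants of the bi-exponential bolus solution.

    C_bolus(t) = A e^{-alpha t} + B e^{-beta t}, with alpha > beta > 0 the
    fast (distribution) and slow (terminal elimination) rate constants and
    A, B the dose/V1-scaled coefficients.
    """

    A: float
    B: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise ValueError("require alpha > beta > 0")
        if not (self.A > 0 and self.B > 0):
            raise ValueError("require A, B > 0")


@dataclass(frozen=True)
class SamplingSchedule:
    """Sample times in minutes after the END of the infusion.

    ``include_predose`` adds a t=0 (concentration 0) record;
    ``mid_infusion_min`` optionally adds one sample during the infusion,
    given in minutes after the START of the infusion.
    """

    post_infusion_min: tuple[float, ...]
    include_predose: bool = True
    mid_infusion_min: float | None = None

    def __post_init__(self) -> None:
        offs = np.asarray(self.post_infusion_min, dtype=float)
        if offs.size == 0 or np.any(offs < 0) or np.any(np.diff(offs) <= 0):
            raise ValueError("offsets must be non-negative and strictly increasing")

    def times_h(self, t_eoi_h: float) -> np.ndarray:
        """All sample times in hours since infusion start."""
        t = [t_eoi_h + off / 60.0 for off in self.post_infusion_min]
        if self.mid_infusion_min is not None:
            if not 0 < self.mid_infusion_min / 60.0 < t_eoi_h:
                raise ValueError("mid-infusion sample must fall inside the infusion")
            t.insert(0, self.mid_infusion_min / 60.0)
        if self.include_predose:
            t.insert(0, 0.0)
        return np.asarray(t, dtype=float)


@dataclass(frozen=True)
class ConcProfile:
    """One subject's measured concentration-time series with its regimen."""

    subject_id: str
    regimen: DoseRegimen
    times_h: np.ndarray
    conc_mg_l: np.ndarray
    cohort: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_mg_l, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "conc_mg_l", c)

    def conc_at_offset_min(self, offset_min: float, atol_h: float = 1e-6) -> float:
        """Concentration at ``offset_min`` minutes after the end of infusion."""
        target = self.regimen.t_eoi_h + offset_min / 60.0
        idx = np.flatnonzero(np.abs(self.times_h - target) <= atol_h)
        if idx.size != 1:
            raise KeyError(
                f"no unique sample at {offset_min} min post-infusion "
                f"for subject {self.subject_id}"
            )
        return float(self.conc_mg_l[idx[0]])


@dataclass(frozen=True)
class CohortSpec:
    """Population-level description of one synthetic cohort.

    CL and terminal volume of distribution (Vz = CL/beta, the TDM-standard
    Vd = Cl/Ke) are drawn independently lognormal with the given means/CVs;
    the terminal half-life ln2*Vz/CL follows.  ``per_kg`` scales CL and Vd
    by body weight (pediatric convention).  ``vss_fraction`` sets the
    steady-state volume as a fraction of Vz (two-compartment: Vss < Vz);
    together with the alpha-phase half-life target it fixes the V1/V2/Q
    split.  ``assay_cv`` is the proportional lognormal measurement error.

    The default ``vss_fraction`` of 0.90 follows the adult vancomycin
    population model of Goti et al. (2018), whose V1/V2/Q estimates imply
    Vss/Vz ~ 0.90.
    """

    name: str
    n_subjects: int
    dose_per_kg: float  # mg/kg
    t_eoi_h: float
    schedule: SamplingSchedule
    cl_mean: float  # L/h, or L/kg/h when per_kg
    cl_cv: float
    vd_mean: float  # terminal Vd (Vz); L, or L/kg when per_kg
    vd_cv: float
    per_kg: bool
    alpha_t_half_h: float
    alpha_t_half_cv: float
    weight_dist: tuple  # ("lognormal", mean, cv) | ("uniform", lo, hi)
    vss_fraction: float = 0.90
    assay_cv: float = 0.075
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for cv in (self.cl_cv, self.vd_cv, self.alpha_t_half_cv):
            if not 0 <= cv < 1:
                raise ValueError("CVs must lie in [0, 1)")
        if self.assay_cv < 0:
            raise ValueError("assay_cv must be non-negative")
        if not 0 < self.vss_fraction < 1:
            raise InfeasibleParameters("vss_fraction must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        sched = d.pop("schedule")
        if isinstance(sched, dict):
            sched = SamplingSchedule(
                post_infusion_min=tuple(sched["post_infusion_min"]),
                include_predose=bool(sched.get("include_predose", True)),
                mid_infusion_min=sched.get("mid_infusion_min"),
            )
        w = d.pop("weight_dist")
        return cls(schedule=sched, weight_dist=tuple(w), **d)


ADULT_SCHEDULE = SamplingSchedule(
    post_infusion_min=(0, 10, 20, 40, 60, 90, 120, 240),
    include_predose=True,
    mid_infusion_min=60.0,
)
PEDIATRIC_SCHEDULE = SamplingSchedule(
    post_infusion_min=(0, 15, 30, 60, 120, 180, 240, 300),
    include_predose=True,
    mid_infusion_min=None,
)


def adult_cohort_spec(
    n_subjects: int = 10, seed: int = 0, assay_cv: float = 0.075
) -> CohortSpec:
    """Adult septic-shock-like cohort: 30 mg/kg over 2 h.

    Population means/CVs follow the adult study summary: CL 4.62 L/h (CV 31%),
    terminal Vd 39.35 L (CV 23%), implying a mean terminal half-life near 6 h.
    """
    return CohortSpec(
        name="adult",
        n_subjects=n_subjects,
        dose_per_kg=30.0,
        t_eoi_h=2.0,
        schedule=ADULT_SCHEDULE,
        cl_mean=4.62,
        cl_cv=1.45 / 4.62,
        vd_mean=39.35,
        vd_cv=8.95 / 39.35,
        per_kg=False,
        alpha_t_half_h=0.5,
        alpha_t_half_cv=0.30,
        weight_dist=("lognormal", 65.0, 0.20),
        assay_cv=assay_cv,
        seed=seed,
    )


def pediatric_cohort_spec(
    n_subjects: int = 14, seed: int = 0, assay_cv: float = 0.075
) -> CohortSpec:
    """Pediatric severe-infection-like cohort: 15 mg/kg over 1 h.

    CL 0.16 L/kg/h (CV 25%), terminal Vd 0.55 L/kg (CV 18%), implying a mean
    terminal half-life near 2.5 h; weights uniform 10-40 kg.
    """
    return CohortSpec(
        name="pediatric",
        n_subjects=n_subjects,
        dose_per_kg=15.0,
        t_eoi_h=1.0,
        schedule=PEDIATRIC_SCHEDULE,
        cl_mean=0.16,
        cl_cv=0.04 / 0.16,
        vd_mean=0.55,
        vd_cv=0.10 / 0.55,
        per_kg=True,
        alpha_t_half_h=0.3,
        alpha_t_half_cv=0.30,
        weight_dist=("uniform", 10.0, 40.0),
        assay_cv=assay_cv,
        seed=seed,
    )


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0:
        return float(mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(math.exp(rng.normal(mu, math.sqrt(sigma2))))


def _draw_weight(rng: np.random.Generator, dist: tuple) -> float:
    kind = dist[0]
    if kind == "lognormal":
        return _lognormal(rng, dist[1], dist[2])
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    raise ValueError(f"unknown weight distribution {kind!r}")


def solve_compartments(
    cl: float, vss: float, alpha: float, beta: float
) -> tuple[float, float, float]:
    """Solve (V1, V2, Q) from (CL, Vss, alpha, beta).

    Uses the closed-form inversion of the hybrid-constant identities
    alpha+beta = k10+k12+k21 and alpha*beta = k10*k21:
    CL/V1 = alpha + beta - alpha*beta*Vss/CL, V2 = Vss - V1,
    Q = alpha*beta*V1*V2/CL.  Feasible iff beta < CL/Vss < alpha.

    Falls back to a fixed V1 = 0.35*Vss split that preserves beta (re-deriving
    alpha) when the requested alpha is unattainable; raises
    ``InfeasibleParameters`` if no positive split exists at all.
    """
    x = cl / vss
    if beta < x < alpha:
        v1 = cl / (alpha + beta - alpha * beta * vss / cl)
        v2 = vss - v1
        q = alpha * beta * v1 * v2 / cl
        if v1 > 0 and v2 > 0 and q > 0:
            return v1, v2, q
    # fallback: fixed central fraction, keep terminal phase, recompute alpha
    v1 = 0.35 * vss
    v2 = vss - v1
    k10 = cl / v1
    if cl <= beta * vss or k10 <= beta:
        raise InfeasibleParameters(
            f"no positive V1/V2/Q split for CL={cl:.4g}, Vss={vss:.4g}, "
            f"alpha={alpha:.4g}, beta={beta:.4g}"
        )
    q = beta * (k10 - beta) * v1 * v2 / (cl - beta * vss)
    warnings.warn(
        "alpha-phase target infeasible; fell back to V1 = 0.35*Vss "
        "(terminal phase preserved, alpha re-derived)",
        RuntimeWarning,
        stacklevel=2,
    )
    return v1, v2, q


def sample_subject(spec: CohortSpec, draw_index: int) -> SubjectPK:
    """Draw one virtual subject; deterministic given (spec.seed, draw_index)."""
    rng = np.random.default_rng([int(spec.seed), int(draw_index)])
    weight = _draw_weight(rng, spec.weight_dist)
    cl = _lognormal(rng, spec.cl_mean, spec.cl_cv)
    vz = _lognormal(rng, spec.vd_mean, spec.vd_cv)
    if spec.per_kg:
        cl *= weight
        vz *= weight
    alpha_t_half = _lognormal(rng, spec.alpha_t_half_h, spec.alpha_t_half_cv)
    beta = cl / vz
    alpha = LN2 / alpha_t_half
    vss = spec.vss_fraction * vz
    v1, v2, q = solve_compartments(cl, vss, alpha, beta)
    return SubjectPK(
        subject_id=f"{spec.name}-{draw_index + 1:03d}",
        weight_kg=weight,
        cl=cl,
        v1=v1,
        v2=v2,
        q=q,
    )


def macro_constants(pk: SubjectPK, regimen: DoseRegimen) -> MacroConstants:
    """Hybrid constants (alpha, beta) and dose-scaled bolus coefficients (A, B)."""
    k10, k12, k21 = pk.k10, pk.k12, pk.k21
    s = k10 + k12 + k21
    p = k10 * k21
    disc = s * s - 4.0 * p  # = (k10+k12-k21)^2 + 4 k12 k21 > 0
    root = math.sqrt(disc)
    alpha = (s + root) / 2.0
    beta = (s - root) / 2.0
    a = regimen.dose_mg / pk.v1 * (alpha - k21) / (alpha - beta)
    b = regimen.dose_mg / pk.v1 * (k21 - beta) / (alpha - beta)
    return MacroConstants(A=a, B=b, alpha=alpha, beta=beta)


def conc_at(pk: SubjectPK, regimen: DoseRegimen, t) -> np.ndarray | float:
    """Noise-free plasma concentration at time(s) ``t`` (hours since start).

    Closed-form constant-rate-infusion solution of the two-compartment model:
    the bolus bi-exponential convolved with a square infusion pulse.  Continuous
    at t = t_eoi, zero at t = 0, strictly decreasing after the infusion ends.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    mc = macro_constants(pk, regimen)
    T = regimen.t_eoi_h
    # infusion-phase coefficients for each exponential term
    ca = mc.A / (mc.alpha * T)
    cb = mc.B / (mc.beta * T)
    tt = np.atleast_1d(t_arr)
    during = tt <= T
    c = np.empty_like(tt)
    td = tt[during]
    c[during] = ca * (1.0 - np.exp(-mc.alpha * td)) + cb * (1.0 - np.exp(-mc.beta * td))
    tp = tt[~during]
    c[~during] = ca * (1.0 - math.exp(-mc.alpha * T)) * np.exp(
        -mc.alpha * (tp - T)
    ) + cb * (1.0 - math.exp(-mc.beta * T)) * np.exp(-mc.beta * (tp - T))
    if t_arr.ndim == 0:
        return float(c[0])
    return c


def simulate_profile(
    pk: SubjectPK,
    regimen: DoseRegimen,
    schedule: SamplingSchedule,
    assay_cv: float,
    rng: np.random.Generator,
    cohort: str = "",
) -> ConcProfile:
    """Sample the subject at the schedule with proportional lognormal noise.

    Measured concentration = true concentration x exp(eps),
    eps ~ N(0, sigma^2), sigma = sqrt(ln(1+assay_cv^2)); the pre-dose zero
    stays exactly zero.
    """
    times = schedule.times_h(regimen.t_eoi_h)
    conc = np.asarray(conc_at(pk, regimen, times), dtype=float)
    if assay_cv > 0:
        sigma = math.sqrt(math.log1p(assay_cv * assay_cv))
        eps = rng.normal(0.0, sigma, size=conc.shape)
        conc = np.where(conc > 0, conc * np.exp(eps), conc)
    return ConcProfile(
        subject_id=pk.subject_id,
        regimen=regimen,
        times_h=times,
        conc_mg_l=conc,
        cohort=cohort,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[ConcProfile], pd.DataFrame]:
    """Generate all profiles plus a ground-truth table.

    The truth table carries each subject's micro-constants and the analytic
    full AUC = dose/CL, the yardstick for recovery tests.
    """
    profiles: list[ConcProfile] = []
    rows = []
    for i in range(spec.n_subjects):
        pk = sample_subject(spec, i)
        regimen = DoseRegimen(dose_mg=spec.dose_per_kg * pk.weight_kg, t_eoi_h=spec.t_eoi_h)
        noise_rng = np.random.default_rng([int(spec.seed), i, 1])
        profiles.append(
            simulate_profile(pk, regimen, spec.schedule, spec.assay_cv, noise_rng, spec.name)
        )
        rows.append(
            {
                "subject_id": pk.subject_id,
                "cohort": spec.name,
                "weight_kg": pk.weight_kg,
                "CL": pk.cl,
                "V1": pk.v1,
                "V2": pk.v2,
                "Q": pk.q,
                "dose_mg": regimen.dose_mg,
                "auc_inf_true": regimen.dose_mg / pk.cl,
            }
        )
    return profiles, pd.DataFrame(rows)


def dense_profile(
    pk: SubjectPK,
    regimen: DoseRegimen,
    step_min: float = 1.0,
    n_half_lives: float = 10.0,
    cohort: str = "",
) -> ConcProfile:
    """Noise-free profile on a dense grid out to ``n_half_lives`` terminal t1/2."""
    mc = macro_constants(pk, regimen)
    t_end = regimen.t_eoi_h + n_half_lives * LN2 / mc.beta
    times = np.arange(0.0, t_end + step_min / 60.0, step_min / 60.0)
    conc = np.asarray(conc_at(pk, regimen, times), dtype=float)
    return ConcProfile(pk.subject_id, regimen, times, conc, cohort)


# ---------------------------------------------------------------------------
# flat-file interchange

def profiles_to_frame(profiles: Iterable[ConcProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, c in zip(p.times_h, p.conc_mg_l):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "time_h": t,
                    "conc_mg_L": c,
                    "dose_mg": p.regimen.dose_mg,
                    "t_eoi_h": p.regimen.t_eoi_h,
                    "cohort": p.cohort,
                }
            )
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[ConcProfile]:
    profiles = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("time_h")
        regimen = DoseRegimen(float(g["dose_mg"].iloc[0]), float(g["t_eoi_h"].iloc[0]))
        cohort = str(g["cohort"].iloc[0]) if "cohort" in g else ""
        profiles.append(
            ConcProfile(
                subject_id=str(sid),
                regimen=regimen,
                times_h=g["time_h"].to_numpy(float),
                conc_mg_l=g["conc_mg_L"].to_numpy(float),
                cohort=cohort,
            )
        )
    return profiles


def write_cohort(
    profiles: Sequence[ConcProfile], truth: pd.DataFrame, outdir: str | Path
) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ppath = outdir / "profiles.csv"
    tpath = outdir / "truth.csv"
    profiles_to_frame(profiles).to_csv(ppath, index=False)
    truth.to_csv(tpath, index=False)
    return ppath, tpath


def read_profiles(path: str | Path) -> list[ConcProfile]:
    return frame_to_profiles(pd.read_csv(path))
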