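"""Noncompartmental reference AUC by the linear-up/log-down trapezoid rule.

The reference standard against which the two-point estimators are judged:
AUC over the sampled interval by linear trapezoids on rising segments and
logarithmic trapezoids on declining segments, a terminal rate constant
(lambda_z) from log-linear regression of the last samples, and the usual
derived parameters CL = dose/AUC, Vz = CL/lambda_z, t1/2 = ln2/lambda_z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simcohort import ConcProfile

LN2 = math.log(2.0)

__all__ = ["NcaResult", "TerminalPhaseError", "lambda_z", "auc_linlog", "auc_inf"]


class TerminalPhaseError(ValueError):
    """Terminal samples do not define a usable (declining) elimination phase."""


@dataclass(frozen=True)
class NcaResult:
    """Reference NCA quantities for one profile.

    ``auc_ref`` is the AUC actually used for the derived parameters:
    ``auc_inf`` in "inf" mode (default), ``auc_tlast`` in "tlast" mode.
    """

    subject_id: str
    auc_tlast: float
    auc_inf: float
    lambda_z: float
    n_lambda_points: int
    cl_ref: float
    vd_ref: float
    t_half_ref: float
    mode: str = "inf"

    @property
    def auc_ref(self) -> float:
        return self.auc_inf if self.mode == "inf" else self.auc_tlast


def lambda_z(profile: ConcProfile, n_points: int = 3) -> float:
    """Terminal rate constant from OLS of ln(conc) on time, last ``n_points``.

    Raises ``TerminalPhaseError`` when the fitted slope is not negative.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points for lambda_z")
    if n_points > len(profile.times_h):
        raise ValueError("n_points exceeds available samples")
    t = profile.times_h[-n_points:]
    c = profile.conc_mg_l[-n_points:]
    if np.any(c <= 0):
        raise TerminalPhaseError("non-positive terminal concentrations")
    fit = stats.linregress(t, np.log(c))
    if fit.slope >= 0:
        raise TerminalPhaseError(f"non-declining terminal phase (slope={fit.slope:.4g})")
    return float(-fit.slope)


def auc_linlog(profile: ConcProfile) -> float:
    """AUC from first to last sample, linear-up/log-down trapezoid rule.

    Per interval: logarithmic trapezoid (C_i - C_{i+1}) dt / ln(C_i/C_{i+1})
    when the segment declines with both endpoints positive, otherwise the
    linear trapezoid (C_i + C_{i+1}) dt / 2 (rising segments and segments
    touching zero).
    """
    t = profile.times_h
    c = profile.conc_mg_l
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    down = (c1 < c0) & (c1 > 0) & (c0 > 0)
    lin = (c0 + c1) * dt / 2.0
    # safe ratio: where not 'down', the log branch is discarded
    ratio = np.where(down, np.divide(c0, np.where(down, c1, 1.0)), math.e)
    log_tr = (c0 - c1) * dt / np.log(ratio)
    return float(np.sum(np.where(down, log_tr, lin)))


def auc_inf(
    profile: ConcProfile, n_lambda_points: int = 3, mode: str = "inf"
) -> NcaResult:
    """Full reference NCA: AUC to infinity plus derived CL, Vz and t1/2.

    AUC(0-inf) = AUC(0-tlast) + C_last/lambda_z; CL = dose/AUC_ref;
    Vz = CL/lambda_z; t1/2 = ln2/lambda_z.
    """
    if mode not in ("inf", "tlast"):
        raise ValueError("mode must be 'inf' or 'tlast'")
    lz = lambda_z(profile, n_lambda_points)
    auc_t = auc_linlog(profile)
    c_last = float(profile.conc_mg_l[-1])
    auc_i = auc_t + c_last / lz
    auc_used = auc_i if mode == "inf" else auc_t
    cl = profile.regimen.dose_mg / auc_used
    return NcaResult(
        subject_id=profile.subject_id,
        auc_tlast=auc_t,
        auc_inf=auc_i,
        lambda_z=lz,
        n_lambda_points=n_lambda_points,
        cl_ref=cl,
        vd_ref=cl / lz,
        t_half_ref=LN2 / lz,
        mode=mode,
    )
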