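import numpy as np
import pytest

from vancauc import simcohort as sc


@pytest.fixture(scope="session")
def adult_mean_pk() -> sc.SubjectPK:
    """One subject at the adult population means (no variability)."""
    spec = _no_cv(sc.adult_cohort_spec(n_subjects=2, seed=0, assay_cv=0.0))
    return sc.sample_subject(spec, 0)


@pytest.fixture(scope="session")
def adult_regimen(adult_mean_pk) -> sc.DoseRegimen:
    return sc.DoseRegimen(dose_mg=30.0 * adult_mean_pk.weight_kg, t_eoi_h=2.0)


def _no_cv(spec: sc.CohortSpec) -> sc.CohortSpec:
    from dataclasses import replace

    w = spec.weight_dist
    if w[0] == "lognormal":
        w = ("lognormal", w[1], 0.0)
    else:  # collapse uniform to its midpoint
        mid = (w[1] + w[2]) / 2
        w = ("uniform", mid, mid)
    return replace(spec, cl_cv=0.0, vd_cv=0.0, alpha_t_half_cv=0.0, weight_dist=w, assay_cv=0.0)


@pytest.fixture(scope="session")
def no_cv():
    return _no_cv


@pytest.fixture(scope="session")
def noise_free_pediatric_cohort():
    spec = sc.pediatric_cohort_spec(n_subjects=30, seed=101, assay_cv=0.0)
    profiles, truth = sc.generate_cohort(spec)
    return spec, profiles, truth


@pytest.fixture(scope="session")
def noise_free_adult_cohort():
    spec = sc.adult_cohort_spec(n_subjects=30, seed=202, assay_cv=0.0)
    profiles, truth = sc.generate_cohort(spec)
    return spec, profiles, truth
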