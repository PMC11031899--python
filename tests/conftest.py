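import numpy as np
import pytest

from taxbenefit import cohort_synth as cs
from taxbenefit import features as ft
from taxbenefit.models import EmbedNetParams, ModelSpec


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient null-effect cohort with 20% censoring."""
    cfg = cs.CohortConfig(n_patients=120, seed=5)
    return cs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return ft.build_feature_set(small_cohort)


def make_patient(
    patient_id="P1",
    age_years=60,
    sex="male",
    histology="intestinal",
    clinical_setting="initially_metastatic",
    prior_gastrectomy=0,
    prior_trastuzumab=0,
    first_line_duration="mid",
    variant_ids=frozenset(),
    pfs_months=2.0,
    pfs_event=1,
    os_months=None,
    os_event=1,
):
    if os_months is None:
        os_months = pfs_months + 6.0
    return cs.Patient(
        patient_id=patient_id,
        age_years=age_years,
        sex=sex,
        histology=histology,
        clinical_setting=clinical_setting,
        prior_gastrectomy=prior_gastrectomy,
        prior_trastuzumab=prior_trastuzumab,
        first_line_duration=first_line_duration,
        variant_ids=frozenset(variant_ids),
        pfs_months=pfs_months,
        pfs_event=pfs_event,
        os_months=os_months,
        os_event=os_event,
    )


@pytest.fixture
def separable_toy_features():
    """Four patients, two variants, linearly separable: carrying variant A
    (and not B) means sensitive."""
    patients = [
        make_patient("T1", variant_ids={"GENEA_SNV"}, pfs_months=8.0),
        make_patient("T2", variant_ids={"GENEA_SNV"}, pfs_months=9.0),
        make_patient("T3", variant_ids={"GENEB_SNV"}, pfs_months=1.0),
        make_patient("T4", variant_ids={"GENEB_SNV"}, pfs_months=1.5),
    ]
    return ft.build_feature_set(patients)


def tiny_embed_params(V=4, k=6, d=3, h=2, seed=0):
    rng = np.random.default_rng(seed)
    return EmbedNetParams(
        E=rng.normal(0, 0.5, (V, d)),
        W1=rng.normal(0, 0.5, (k + d, h)),
        b1=rng.normal(0, 0.5, h),
        w2=rng.normal(0, 0.5, h),
        b2=float(rng.normal()),
    )
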