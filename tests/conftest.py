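import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_table():
    from csfenergy.reference import load_reference_table

    return load_reference_table()


@pytest.fixture(scope="session")
def default_specs():
    from csfenergy.synthcohort import load_default_specs

    specs, plumbing = load_default_specs()
    return specs, plumbing


@pytest.fixture(scope="session")
def small_cohort():
    """One-tenth-size cohort (818 records), shared across tests."""
    from csfenergy.synthcohort import generate_cohort

    return generate_cohort(seed=7, scale=0.1)


@pytest.fixture()
def control_record():
    from csfenergy.records import CSFRecord

    return CSFRecord(
        record_id="ctl-1", age_years=35.0,
        lactate_csf=1.2, glucose_csf=3.2, glucose_serum=5.4,
        tp_csf=350.0, albumin_csf=180.0, albumin_serum=42000.0,
        beta2m_csf=1.1, leukocytes=2.0, erythrocytes=1.0,
        fraction_lymphocyte=0.7, fraction_monocyte=0.3, fraction_granulocyte=0.0,
        malignant_cells_present=False, it_igg=0.0, it_iga=0.0, it_igm=0.0,
    )
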