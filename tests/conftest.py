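import dataclasses

import pytest

import hepascore as h


def make_record(**overrides) -> h.ClinicalRecord:
    """A baseline patient with every scored factor absent (0 points)."""
    base = dict(
        age_years=40.0, sex="male", asa_class=1, diagnosis="other",
        right_trisectionectomy=False, inr=1.0, ggt_u_per_l=30.0,
        platelets_per_nl=250.0, creatinine_mg_dl=1.0, bilirubin_mg_dl=1.0,
        on_dialysis=False,
    )
    base.update(overrides)
    return h.ClinicalRecord(**base)


@pytest.fixture(scope="session")
def default_spec() -> h.CohortSpec:
    spec = h.CohortSpec()
    spec.validate()
    return spec


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """A scored synthetic cohort of 400 patients, fixed seed."""
    df = h.generate_cohort(dataclasses.replace(default_spec, n=400), seed=7)
    scored, rejects = h.score_cohort(df)
    assert rejects.empty
    return scored


@pytest.fixture(scope="session")
def large_cohort(default_spec):
    """A 100k-patient cohort for law-of-large-numbers checks (shared)."""
    return h.generate_cohort(dataclasses.replace(default_spec, n=100_000), seed=11)
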