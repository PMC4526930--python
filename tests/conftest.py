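import pytest

from triagekit import (
    Association,
    CaseFinding,
    Demographics,
    DiagnosisConcept,
    EngineConfig,
    FindingConcept,
    KnowledgeBase,
    PatientCase,
    VitalSigns,
)


@pytest.fixture()
def config():
    return EngineConfig()


@pytest.fixture()
def tiny_kb():
    """One diagnosis, one finding, one very-common association."""
    return KnowledgeBase(
        version="test",
        findings=[
            FindingConcept(
                id="cough",
                label="severe cough",
                synonyms=["bad cough"],
                intrinsic_severity_range=(2, 4),
            )
        ],
        diagnoses=[
            DiagnosisConcept(
                id="asthma",
                label="asthma",
                baseline_prevalence=0.01,
                severity_range=(2, 4),
            )
        ],
        associations=[
            Association(
                diagnosis_id="asthma",
                finding_id="cough",
                frequency_category="very_common",
                severity_for_diagnosis=3,
            )
        ],
    )


@pytest.fixture()
def three_dx_kb():
    """Three diagnoses sharing/differing in findings; hand-computable scores."""
    findings = [
        FindingConcept(id=f, label=f.replace("_", " "))
        for f in ["chest_pain", "dyspnea", "fever", "rash"]
    ]
    # sob resolves via synonym
    findings[1].synonyms = ["SOB", "shortness of breath"]
    diagnoses = [
        DiagnosisConcept(
            id="mi", label="myocardial infarction",
            baseline_prevalence=0.02, severity_range=(1, 2),
            critical_tests=["electrocardiogram"],
        ),
        DiagnosisConcept(
            id="pneumonia", label="pneumonia",
            baseline_prevalence=0.05, severity_range=(2, 4),
        ),
        DiagnosisConcept(
            id="dermatitis", label="contact dermatitis",
            baseline_prevalence=0.08, severity_range=(4, 5),
        ),
    ]
    associations = [
        Association(diagnosis_id="mi", finding_id="chest_pain",
                    frequency_category="very_common", severity_for_diagnosis=1),
        Association(diagnosis_id="mi", finding_id="dyspnea",
                    frequency_category="common", severity_for_diagnosis=2),
        Association(diagnosis_id="pneumonia", finding_id="dyspnea",
                    frequency_category="very_common", severity_for_diagnosis=3),
        Association(diagnosis_id="pneumonia", finding_id="fever",
                    frequency_category="very_common", severity_for_diagnosis=3),
        Association(diagnosis_id="pneumonia", finding_id="chest_pain",
                    frequency_category="common", severity_for_diagnosis=2),
        Association(diagnosis_id="dermatitis", finding_id="rash",
                    frequency_category="key", severity_for_diagnosis=5),
    ]
    return KnowledgeBase(version="test3", findings=findings,
                         diagnoses=diagnoses, associations=associations)


def make_case(finding_ids, age=30.0, sex="male", case_id="c1", duration=None,
              vitals=None):
    return PatientCase(
        case_id=case_id,
        demographics=Demographics(age=age, sex=sex),
        findings=[
            CaseFinding(finding_id=f, duration_hours=duration)
            for f in finding_ids
        ],
        vitals=vitals or VitalSigns(),
    )


@pytest.fixture()
def case_factory():
    return make_case
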