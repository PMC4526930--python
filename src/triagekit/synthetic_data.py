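"""Synthetic knowledge bases and case vignettes, plus the published fixture.

The proprietary curated database and the copyrighted handbook vignettes are
not redistributable, so testing uses synthetic stand-ins that share the
statistical structure the engine assumes: diagnoses with log-uniform
baseline prevalences and curated-style severity ranges, associations with
frequency categories drawn from a fixed mix, and cases sampled from a chosen
"true" diagnosis by including each associated finding with its category
probability (times demographic modifiers), plus spurious-finding and
dropout noise.  Because generator and engine share the likelihood model,
the engine must recover the true diagnosis and severity well; the recovery
tests are regression guards, not clinical claims.

``table5_fixture`` is the published 73-case 5x5 confusion matrix of engine
versus reference scores, the input to the agreement-harness reproduction.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .case_model import CaseFinding, Demographics, PatientCase, VitalSigns
from .errors import ConfigurationError
from .evaluation import ConfusionMatrix
from .knowledge_base import (
    Association,
    DemographicModifier,
    DiagnosisConcept,
    FindingConcept,
    KnowledgeBase,
)

#: Frequency-category mix used when synthesizing associations: chosen to
#: exercise every scoring branch (including the rare 'key' edge).
DEFAULT_CATEGORY_MIX = {
    "very_common": 0.20,
    "common": 0.40,
    "uncommon": 0.30,
    "rare": 0.08,
    "key": 0.02,
}

#: Sampling probability per category when generating presentations
#: (midpoints of the curated ranges; 'key' behaves as very common).
CATEGORY_SAMPLING_P = {
    "key": 0.75,
    "very_common": 0.75,
    "common": 0.30,
    "uncommon": 0.055,
    "rare": 0.005,
}

PREVALENCE_RANGE = (1e-4, 1e-1)  # log-uniform draw
P_CRITICAL_TEST = 0.8  # chance an urgent/emergent diagnosis lists a test


class SyntheticTruth(BaseModel):
    model_config = ConfigDict(extra="forbid")

    case_id: str
    true_diagnosis_id: str
    true_severity: int


def generate_kb(
    n_diagnoses: int,
    n_findings: int,
    assoc_per_diagnosis: int,
    severity_mix: Optional[Sequence[float]] = None,
    seed: int = 0,
    category_mix: Optional[dict[str, float]] = None,
    p_demographic_modifier: float = 0.15,
) -> KnowledgeBase:
    """Sample a valid synthetic knowledge base; deterministic given seed.

    ``severity_mix`` is a distribution over severities 1-5 for the severe
    end of each diagnosis's range (uniform by default); the mild end extends
    it by 0-2 levels.  A fraction of associations get a U-shaped age
    modifier (more likely in the very young and the very old).
    """
    if n_diagnoses < 1:
        raise ConfigurationError("n_diagnoses must be >= 1")
    if n_findings < assoc_per_diagnosis:
        raise ConfigurationError(
            "n_findings must be >= assoc_per_diagnosis so associations "
            "can be distinct"
        )
    mix = np.asarray(severity_mix if severity_mix is not None else [0.2] * 5, float)
    if mix.shape != (5,) or mix.sum() <= 0:
        raise ConfigurationError("severity_mix must be 5 non-negative weights")
    mix = mix / mix.sum()
    cats = category_mix or DEFAULT_CATEGORY_MIX
    cat_names = list(cats)
    cat_p = np.asarray([cats[c] for c in cat_names], float)
    cat_p = cat_p / cat_p.sum()

    rng = np.random.default_rng(seed)
    findings = []
    for i in range(n_findings):
        severe = int(rng.integers(1, 6))
        mild = int(min(5, severe + rng.integers(0, 3)))
        findings.append(
            FindingConcept(
                id=f"f{i:04d}",
                label=f"finding {i:04d}",
                synonyms=[f"syn {i:04d}"] if rng.random() < 0.3 else [],
                intrinsic_severity_range=(severe, mild),
            )
        )

    lo, hi = PREVALENCE_RANGE
    diagnoses = []
    associations = []
    for i in range(n_diagnoses):
        severe = int(rng.choice(5, p=mix)) + 1
        mild = int(min(5, severe + rng.integers(0, 3)))
        prevalence = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        critical = (
            ["critical test"]
            if severe <= 2 and rng.random() < P_CRITICAL_TEST
            else []
        )
        did = f"d{i:04d}"
        diagnoses.append(
            DiagnosisConcept(
                id=did,
                label=f"diagnosis {i:04d}",
                baseline_prevalence=prevalence,
                severity_range=(severe, mild),
                critical_tests=critical,
            )
        )
        linked = rng.choice(n_findings, size=assoc_per_diagnosis, replace=False)
        for fi in sorted(int(x) for x in linked):
            modifiers = []
            if rng.random() < p_demographic_modifier:
                # U-shaped age effect: common at the extremes of age
                modifiers = [
                    DemographicModifier(age_lo=0, age_hi=5, multiplier=2.0),
                    DemographicModifier(age_lo=18, age_hi=50, multiplier=0.5),
                    DemographicModifier(age_lo=65, age_hi=120, multiplier=2.0),
                ]
            associations.append(
                Association(
                    diagnosis_id=did,
                    finding_id=f"f{fi:04d}",
                    frequency_category=str(rng.choice(cat_names, p=cat_p)),
                    severity_for_diagnosis=int(rng.integers(severe, mild + 1)),
                    demographic_modifiers=modifiers,
                )
            )
    return KnowledgeBase(
        version=f"synthetic-seed{seed}",
        findings=findings,
        diagnoses=diagnoses,
        associations=associations,
    )


def generate_cases(
    kb: KnowledgeBase,
    n_cases: int,
    extra_finding_rate: float = 0.05,
    dropout_rate: float = 0.1,
    seed: int = 0,
    age_range: tuple[float, float] = (0.0, 90.0),
) -> list[tuple[PatientCase, SyntheticTruth]]:
    """Sample presentations from the KB's own generative model.

    Per case: draw the true diagnosis proportional to prevalence; include
    each associated finding independently with its category sampling
    probability times the demographic multiplier (clamped to 1); drop
    included findings at ``dropout_rate``; add a Poisson(``extra_finding_rate``)
    number of spurious unassociated findings; resample until at least one
    finding remains.  Deterministic given seed.
    """
    from .knowledge_base import demographic_multiplier
    from .triage import diagnosis_case_severity

    rng = np.random.default_rng(seed)
    prev = np.asarray([d.baseline_prevalence for d in kb.diagnoses], float)
    prev = prev / prev.sum()
    all_finding_ids = [f.id for f in kb.findings]

    out: list[tuple[PatientCase, SyntheticTruth]] = []
    for c in range(n_cases):
        d = kb.diagnoses[int(rng.choice(len(kb.diagnoses), p=prev))]
        age = float(rng.uniform(*age_range))
        sex = "female" if rng.random() < 0.5 else "male"
        assocs = kb.associations_for(d.id)
        assoc_fids = {a.finding_id for a in assocs}

        finding_ids: list[str] = []
        for _ in range(1000):  # resample guard: >= 1 finding required
            finding_ids = []
            for a in assocs:
                p = CATEGORY_SAMPLING_P[a.frequency_category]
                p = min(1.0, p * demographic_multiplier(a.demographic_modifiers, age, sex))
                if rng.random() < p and rng.random() >= dropout_rate:
                    finding_ids.append(a.finding_id)
            n_extra = int(rng.poisson(extra_finding_rate))
            spurious = [f for f in all_finding_ids if f not in assoc_fids]
            if n_extra and spurious:
                picks = rng.choice(len(spurious), size=min(n_extra, len(spurious)),
                                   replace=False)
                finding_ids.extend(spurious[int(i)] for i in sorted(picks))
            if finding_ids:
                break
        else:  # pragma: no cover - requires pathological parameters
            raise ConfigurationError(
                f"could not sample a non-empty presentation for {d.id}"
            )

        case = PatientCase(
            case_id=f"case{c:05d}",
            demographics=Demographics(age=age, sex=sex),
            findings=[
                CaseFinding(
                    finding_id=fid,
                    duration_hours=float(rng.exponential(48.0)),
                )
                for fid in finding_ids
            ],
            vitals=VitalSigns(),
        )
        truth = SyntheticTruth(
            case_id=case.case_id,
            true_diagnosis_id=d.id,
            true_severity=diagnosis_case_severity(kb, case, d.id),
        )
        out.append((case, truth))
    return out


def table5_fixture() -> ConfusionMatrix:
    """Published 73-vignette confusion matrix: rows = engine score, columns
    = reference (ESI) score; trace 69, n 73."""
    return ConfusionMatrix(
        counts=[
            [13, 1, 0, 0, 0],
            [0, 26, 0, 0, 0],
            [0, 0, 20, 0, 1],
            [0, 1, 1, 4, 0],
            [0, 0, 0, 0, 6],
        ],
        k=5,
    )
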