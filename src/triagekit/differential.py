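"""Differential-diagnosis ranking.

Every diagnosis in the knowledge base is scored for the case with a
naive-Bayes-style product: its baseline prevalence times, for each case
finding, the likelihood that the diagnosis presents with that finding.  The
likelihood of an associated finding is the representative probability of its
curated frequency category, scaled by any matching demographic modifiers and
clamped to 1; a finding with no association contributes the small uniform
epsilon; each 'key' finding of the diagnosis that the case lacks multiplies
the score by the missing-key penalty.  Scores are sorted (deterministic
tie-break), truncated to the top K and renormalized into weights.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .case_model import PatientCase
from .config import EngineConfig
from .errors import DegenerateCaseError
from .knowledge_base import (
    KnowledgeBase,
    demographic_multiplier,
    frequency_to_probability,
)


class DifferentialEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    diagnosis_id: str
    raw_score: float = Field(ge=0)
    weight: float = Field(gt=0, le=1)
    rank: int = Field(ge=1)


class DifferentialList(BaseModel):
    model_config = ConfigDict(extra="forbid")

    case_id: str
    K: int
    entries: list[DifferentialEntry]

    def weights(self) -> dict[str, float]:
        return {e.diagnosis_id: e.weight for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [e.model_dump() for e in self.entries],
            columns=["rank", "diagnosis_id", "raw_score", "weight"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def diagnosis_score(
    kb: KnowledgeBase,
    case: PatientCase,
    diagnosis_id: str,
    config: EngineConfig | None = None,
) -> float:
    """Unnormalized case likelihood score for one diagnosis.

    score = prevalence(d) * prod_f L(f | d, demographics) * pi^(missing keys)
    with L = min(1, p_category * demographic multiplier) for associated
    findings and L = epsilon otherwise.
    """
    cfg = config or EngineConfig()
    d = kb.diagnosis(diagnosis_id)
    age, sex = case.demographics.age, case.demographics.sex
    present = set(case.known_finding_ids())

    score = d.baseline_prevalence
    for f in case.findings:
        assoc = kb.association(diagnosis_id, f.finding_id)
        if assoc is None:
            score *= cfg.unmatched_finding_epsilon
        else:
            p = frequency_to_probability(assoc.frequency_category, cfg)
            mult = demographic_multiplier(assoc.demographic_modifiers, age, sex)
            score *= min(1.0, p * mult)
    for assoc in kb.associations_for(diagnosis_id):
        if assoc.frequency_category == "key" and assoc.finding_id not in present:
            score *= cfg.key_missing_penalty
    return score


def build_differential(
    kb: KnowledgeBase,
    case: PatientCase,
    K: Optional[int] = None,
    config: EngineConfig | None = None,
) -> DifferentialList:
    """Score every diagnosis, rank deterministically, keep the top K.

    Ties in raw score break by higher baseline prevalence, then by id, so
    results are identical across runs and platforms.  Weights over the
    truncated list sum to one; an all-zero score vector (possible only by
    numeric underflow) cannot be normalized and raises.
    """
    cfg = config or EngineConfig()
    k = K if K is not None else cfg.top_k
    if k < 1:
        raise DegenerateCaseError("K must be >= 1")
    if not kb.diagnoses:
        raise DegenerateCaseError("KB has no diagnoses")

    scored = sorted(
        (
            (diagnosis_score(kb, case, d.id, cfg), d.baseline_prevalence, d.id)
            for d in kb.diagnoses
        ),
        key=lambda t: (-t[0], -t[1], t[2]),
    )[:k]
    total = sum(s for s, _, _ in scored)
    if total <= 0.0:
        raise DegenerateCaseError(
            f"case {case.case_id!r}: all diagnosis scores are zero "
            "(numeric underflow); cannot normalize weights"
        )
    entries = [
        DifferentialEntry(
            diagnosis_id=did, raw_score=s, weight=s / total, rank=i + 1
        )
        for i, (s, _, did) in enumerate(scored)
        if s > 0.0
    ]
    return DifferentialList(case_id=case.case_id, K=k, entries=entries)
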