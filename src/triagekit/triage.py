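"""Severity aggregation and the mid-band rounding rule.

The pipeline: build the weighted differential, assign each top-K diagnosis a
whole-number case severity, average those severities under the differential
weights into a fractional score in [1, 5], then convert to the final integer
level.  A fractional part in the configured middle band (default the closed
interval [0.40, 0.60]) is ambiguous and is resolved by context: a critical
test on an urgent/emergent diagnosis in the differential, or a short symptom
duration, rounds toward the more severe level (numerically smaller, since
level 1 is "revive/unstable"); otherwise the score rounds toward the less
severe level.  Fractions outside the band round to the nearest integer.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field

from .case_model import PatientCase
from .config import EngineConfig
from .differential import DifferentialList, build_differential
from .errors import ContractError
from .knowledge_base import KnowledgeBase

RoundingTrigger = Literal[
    "none", "critical_test_or_short_duration", "no_critical_long_duration"
]


class TriageResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    case_id: str
    fractional_severity: float = Field(ge=1.0, le=5.0)
    final_severity: int = Field(ge=1, le=5)
    rounding_trigger: RoundingTrigger
    differential: DifferentialList
    notes: list[str] = Field(default_factory=list)


def diagnosis_case_severity(
    kb: KnowledgeBase, case: PatientCase, diagnosis_id: str
) -> int:
    """Whole-number severity of one diagnosis for this presentation.

    The most severe (minimum) curated per-association severity among the
    case's matched findings, clamped into the diagnosis's own severity
    range.  With no matched finding the rounded midpoint of the range is
    used; an exact half rounds toward the severe end, consistent with the
    engine's safety-first rounding direction.
    """
    d = kb.diagnosis(diagnosis_id)
    severe, mild = d.severity_range
    matched = [
        assoc.severity_for_diagnosis
        for f in case.findings
        if (assoc := kb.association(diagnosis_id, f.finding_id)) is not None
    ]
    if matched:
        return min(mild, max(severe, min(matched)))
    mid = (severe + mild) / 2.0
    return math.floor(mid) if (mid - math.floor(mid)) == 0.5 else round(mid)


def aggregate_severity(
    differential: DifferentialList, severities: Mapping[str, int]
) -> float:
    """Weight-averaged severity over the differential; lies in [1, 5]."""
    missing = [e.diagnosis_id for e in differential.entries if e.diagnosis_id not in severities]
    if missing:
        raise ContractError(f"no severity provided for: {', '.join(missing)}")
    return sum(e.weight * severities[e.diagnosis_id] for e in differential.entries)


def round_severity(
    fractional: float,
    has_critical_test: bool = False,
    short_duration: bool = False,
    band: tuple[float, float] | None = None,
) -> tuple[int, RoundingTrigger]:
    """Convert a fractional severity to an integer level 1-5.

    Returns the level and which rule fired.  Inside the closed mid band the
    context decides: critical test or short duration rounds toward level 1
    (more severe), otherwise toward level 5.  Outside the band the nearest
    integer wins (the default band contains .5, so no half-way tie arises).
    """
    lo, hi = band if band is not None else (0.40, 0.60)
    frac = fractional - math.floor(fractional)
    # tolerance so closed band endpoints survive binary-float subtraction
    eps = 1e-9
    if lo - eps <= frac <= hi + eps and frac > eps:
        if has_critical_test or short_duration:
            level = math.floor(fractional)
            trigger: RoundingTrigger = "critical_test_or_short_duration"
        else:
            level = math.ceil(fractional)
            trigger = "no_critical_long_duration"
    else:
        level = math.floor(fractional) if frac < 0.5 else math.ceil(fractional)
        trigger = "none"
    return min(5, max(1, level)), trigger


def triage_case(
    kb: KnowledgeBase,
    case: PatientCase,
    config: EngineConfig | None = None,
    K: Optional[int] = None,
) -> TriageResult:
    """Full scoring pipeline for one case, with provenance."""
    cfg = config or EngineConfig()
    differential = build_differential(kb, case, K=K, config=cfg)
    severities = {
        e.diagnosis_id: diagnosis_case_severity(kb, case, e.diagnosis_id)
        for e in differential.entries
    }
    fractional = aggregate_severity(differential, severities)

    notes: list[str] = []
    present = set(f.finding_id for f in case.findings)
    override = next(
        (f for f in cfg.revive_override_findings if f in present), None
    )
    if override is not None:
        notes.append(f"hard override: finding {override!r} forces level 1")
        return TriageResult(
            case_id=case.case_id,
            fractional_severity=fractional,
            final_severity=1,
            rounding_trigger="none",
            differential=differential,
            notes=notes,
        )

    critical = [
        e.diagnosis_id
        for e in differential.entries
        if kb.diagnosis(e.diagnosis_id).base_severity <= cfg.urgent_severity_cutoff
        and kb.diagnosis(e.diagnosis_id).critical_tests
    ]
    has_critical = bool(critical)
    min_dur = case.min_known_duration()
    short = min_dur is not None and min_dur < cfg.short_duration_hours

    final, trigger = round_severity(
        fractional, has_critical, short, band=cfg.rounding_band
    )
    if critical:
        notes.append(
            "critical tests recommended for urgent/emergent diagnoses: "
            + ", ".join(sorted(critical)[:5])
        )
    if min_dur is not None:
        notes.append(f"minimum known finding duration {min_dur:g} h")
    for lab in case.unknown_labels():
        notes.append(f"unmatched reported finding retained: {lab!r}")
    return TriageResult(
        case_id=case.case_id,
        fractional_severity=fractional,
        final_severity=final,
        rounding_trigger=trigger,
        differential=differential,
        notes=notes,
    )
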