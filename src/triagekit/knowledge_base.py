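"""Curated diagnosis-finding knowledge graph: types, I/O, validation, queries.

The knowledge base is a bipartite graph.  One side holds findings (signs,
symptoms, vital-sign derangements), each with a physician-assigned intrinsic
severity range on the 5-level scale (1 = most severe, "revive/unstable";
5 = least, "referred").  The other side holds diagnoses, each with a baseline
prevalence, a severity range, and an optional list of critical tests.  Edges
are associations carrying a curated frequency category (key / very common /
common / uncommon / rare), the severity the finding implies for that
diagnosis, and optional demographic modifiers that scale the edge likelihood
multiplicatively by patient age band and sex.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .config import FREQUENCY_CATEGORIES, EngineConfig
from .errors import (
    LookupError_,
    ReferentialIntegrityError,
    SchemaError,
    VocabularyError,
)

SeverityPair = tuple[int, int]

_WS_PUNCT = re.compile(r"[\s\W_]+")


def normalize_label(label: str) -> str:
    """Canonical form used for label/synonym lookup: lower-cased, with
    whitespace and punctuation collapsed to single spaces."""
    return _WS_PUNCT.sub(" ", label.strip().lower()).strip()


def _check_severity_pair(pair: SeverityPair, what: str) -> None:
    severe, mild = pair
    if not (1 <= severe <= mild <= 5):
        raise ValueError(
            f"{what} must satisfy 1 <= severe <= mild <= 5, got {pair}"
        )


class FindingConcept(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    label: str
    synonyms: list[str] = Field(default_factory=list)
    #: (severe end, mild end); 1 is the most severe level.
    intrinsic_severity_range: SeverityPair = (1, 5)

    @model_validator(mode="after")
    def _check(self) -> "FindingConcept":
        _check_severity_pair(self.intrinsic_severity_range,
                             f"finding {self.id!r} intrinsic_severity_range")
        return self


class DiagnosisConcept(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    label: str
    baseline_prevalence: float = Field(gt=0.0, le=1.0)
    severity_range: SeverityPair
    critical_tests: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "DiagnosisConcept":
        _check_severity_pair(self.severity_range,
                             f"diagnosis {self.id!r} severity_range")
        return self

    @property
    def base_severity(self) -> int:
        """Severe end of the curated range; drives the urgent/emergent cut."""
        return self.severity_range[0]


class DemographicModifier(BaseModel):
    model_config = ConfigDict(extra="forbid")

    age_lo: float = Field(ge=0)
    age_hi: float
    sex: Literal["female", "male", "any"] = "any"
    multiplier: float = Field(gt=0)
    # Accepted in the schema but inactive by default: the curation model
    # mentions race and symptom duration as edge factors without a form.
    race: Optional[str] = None
    duration_band_hours: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "DemographicModifier":
        if self.age_hi <= self.age_lo:
            raise ValueError("age_hi must exceed age_lo")
        return self

    def matches(self, age: float, sex: str) -> bool:
        if not (self.age_lo <= age < self.age_hi):
            return False
        return self.sex == "any" or self.sex == sex


class Association(BaseModel):
    model_config = ConfigDict(extra="forbid")

    diagnosis_id: str
    finding_id: str
    frequency_category: str
    #: Severity this finding carries when presenting with this diagnosis.
    severity_for_diagnosis: int = Field(ge=1, le=5)
    demographic_modifiers: list[DemographicModifier] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "Association":
        if self.frequency_category not in FREQUENCY_CATEGORIES:
            raise ValueError(
                f"frequency_category {self.frequency_category!r} not in "
                f"{FREQUENCY_CATEGORIES}"
            )
        return self


class KnowledgeBase(BaseModel):
    model_config = ConfigDict(extra="forbid")

    version: str = "0"
    findings: list[FindingConcept] = Field(default_factory=list)
    diagnoses: list[DiagnosisConcept] = Field(default_factory=list)
    associations: list[Association] = Field(default_factory=list)

    # -- indexed views (rebuilt lazily; pydantic models are mutable) -------
    def finding(self, finding_id: str) -> FindingConcept:
        try:
            return self._finding_index[finding_id]
        except KeyError:
            raise LookupError_(f"unknown finding id {finding_id!r}") from None

    def diagnosis(self, diagnosis_id: str) -> DiagnosisConcept:
        try:
            return self._diagnosis_index[diagnosis_id]
        except KeyError:
            raise LookupError_(f"unknown diagnosis id {diagnosis_id!r}") from None

    def associations_for(self, diagnosis_id: str) -> list[Association]:
        return self._assoc_by_diagnosis.get(diagnosis_id, [])

    def association(self, diagnosis_id: str, finding_id: str) -> Optional[Association]:
        return self._assoc_index.get((diagnosis_id, finding_id))

    @property
    def _finding_index(self) -> dict[str, FindingConcept]:
        return {f.id: f for f in self.findings}

    @property
    def _diagnosis_index(self) -> dict[str, DiagnosisConcept]:
        return {d.id: d for d in self.diagnoses}

    @property
    def _assoc_index(self) -> dict[tuple[str, str], Association]:
        return {(a.diagnosis_id, a.finding_id): a for a in self.associations}

    @property
    def _assoc_by_diagnosis(self) -> dict[str, list[Association]]:
        out: dict[str, list[Association]] = {}
        for a in self.associations:
            out.setdefault(a.diagnosis_id, []).append(a)
        return out

    def label_index(self) -> dict[str, str]:
        """Normalized label/synonym -> finding id."""
        idx: dict[str, str] = {}
        for f in self.findings:
            for lab in [f.label, *f.synonyms]:
                idx[normalize_label(lab)] = f.id
        return idx


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_kb(path: str | Path, strict: bool = True) -> KnowledgeBase:
    """Load and fully validate a knowledge base from a JSON document.

    Raises :class:`SchemaError` naming the offending record/field, or
    :class:`ReferentialIntegrityError` listing unresolved ids.  In lenient
    mode (``strict=False``) unknown keys are dropped with a warning instead
    of rejected.
    """
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"KB file not found: {p}")
    try:
        raw = json.loads(p.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"KB file is not valid JSON: {exc}") from exc
    return kb_from_dict(raw, strict=strict)


def kb_from_dict(raw: dict, strict: bool = True) -> KnowledgeBase:
    if not isinstance(raw, dict):
        raise SchemaError("KB document must be a JSON object")
    if not strict:
        raw = _strip_unknown_keys(raw)
    try:
        kb = KnowledgeBase(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise SchemaError(f"KB schema violation at {loc}: {first['msg']}") from exc
    violations = validate_kb(kb)
    dangling = [v for v in violations if "unresolved" in v]
    if dangling:
        ids = []
        for v in dangling:
            ids.extend(re.findall(r"'([^']+)'", v))
        raise ReferentialIntegrityError(sorted(set(ids)))
    if violations:
        raise SchemaError("; ".join(violations))
    return kb


def _strip_unknown_keys(raw: dict) -> dict:
    import warnings

    known_top = {"version", "findings", "diagnoses", "associations"}
    extra = set(raw) - known_top
    if extra:
        warnings.warn(f"ignoring unknown KB keys: {sorted(extra)}", stacklevel=3)
    out = {k: raw[k] for k in known_top & set(raw)}
    field_sets = {
        "findings": set(FindingConcept.model_fields),
        "diagnoses": set(DiagnosisConcept.model_fields),
        "associations": set(Association.model_fields),
    }
    for section, allowed in field_sets.items():
        recs = out.get(section)
        if isinstance(recs, list):
            out[section] = [
                {k: v for k, v in r.items() if k in allowed}
                if isinstance(r, dict) else r
                for r in recs
            ]
    return out


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(kb.model_dump(mode="json"), indent=1, sort_keys=True),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_kb(kb: KnowledgeBase) -> list[str]:
    """Return a list of invariant violations; empty iff the KB is sound.

    Never raises: each violation names the offending record and rule.
    """
    out: list[str] = []

    def pair_ok(pair: SeverityPair) -> bool:
        severe, mild = pair
        return 1 <= severe <= mild <= 5

    seen_f: set[str] = set()
    for f in kb.findings:
        if f.id in seen_f:
            out.append(f"finding '{f.id}': duplicate id")
        seen_f.add(f.id)
        if not pair_ok(f.intrinsic_severity_range):
            out.append(
                f"finding '{f.id}': intrinsic_severity_range "
                f"{f.intrinsic_severity_range} violates 1 <= severe <= mild <= 5"
            )
    seen_d: set[str] = set()
    for d in kb.diagnoses:
        if d.id in seen_d:
            out.append(f"diagnosis '{d.id}': duplicate id")
        seen_d.add(d.id)
        if not pair_ok(d.severity_range):
            out.append(
                f"diagnosis '{d.id}': severity_range {d.severity_range} "
                "violates 1 <= severe <= mild <= 5"
            )
        if not (0.0 < d.baseline_prevalence <= 1.0):
            out.append(
                f"diagnosis '{d.id}': baseline_prevalence "
                f"{d.baseline_prevalence} outside (0, 1]"
            )

    # one normalized label/synonym must resolve to exactly one finding
    label_owner: dict[str, str] = {}
    for f in kb.findings:
        for lab in [f.label, *f.synonyms]:
            norm = normalize_label(lab)
            owner = label_owner.setdefault(norm, f.id)
            if owner != f.id:
                out.append(
                    f"finding '{f.id}': label/synonym {lab!r} collides with "
                    f"finding '{owner}'"
                )

    seen_edge: set[tuple[str, str]] = set()
    linked: set[str] = set()
    for a in kb.associations:
        key = (a.diagnosis_id, a.finding_id)
        edge = f"{a.diagnosis_id}->{a.finding_id}"
        if key in seen_edge:
            out.append(f"association {edge}: duplicate edge")
        seen_edge.add(key)
        if a.diagnosis_id not in seen_d:
            out.append(f"association {edge}: unresolved diagnosis '{a.diagnosis_id}'")
        if a.finding_id not in seen_f:
            out.append(f"association {edge}: unresolved finding '{a.finding_id}'")
        linked.add(a.diagnosis_id)
        # age bands must not overlap within one association (per sex track)
        mods = sorted(a.demographic_modifiers, key=lambda m: m.age_lo)
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                sexes_clash = (
                    m1.sex == m2.sex or m1.sex == "any" or m2.sex == "any"
                )
                if sexes_clash and m2.age_lo < m1.age_hi:
                    out.append(
                        f"association {edge}: overlapping age bands "
                        f"[{m1.age_lo},{m1.age_hi}) and [{m2.age_lo},{m2.age_hi})"
                    )
    for d in kb.diagnoses:
        if d.id not in linked:
            out.append(f"diagnosis '{d.id}': has no associations")
    return out


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def frequency_to_probability(category: str, config: EngineConfig | None = None) -> float:
    """Representative presentation probability for a curated category.

    Defaults are the arithmetic midpoints of the curated ranges; 'key' maps
    to the very_common probability (its required-ness is enforced by the
    missing-key penalty during scoring, not here).
    """
    cfg = config or EngineConfig()
    if category not in FREQUENCY_CATEGORIES:
        raise VocabularyError(
            f"unknown frequency category {category!r}; expected one of "
            f"{FREQUENCY_CATEGORIES}"
        )
    return cfg.frequency_probabilities[category]


def demographic_multiplier(
    modifiers: Iterable[DemographicModifier], age: float, sex: str = "unknown"
) -> float:
    """Product of the multipliers of every modifier matching age and sex.

    1.0 when nothing matches; order-independent.  Callers clamp the modified
    likelihood to <= 1.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    out = 1.0
    for m in modifiers:
        if m.matches(age, sex):
            out *= m.multiplier
    return out
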