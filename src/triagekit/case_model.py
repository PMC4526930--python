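"""Structured patient presentations and their normalization.

A :class:`PatientCase` is demographics + at least one finding + optional
vital signs.  Findings arrive as free labels and are resolved against the
knowledge base's label/synonym index; labels with no match are retained,
flagged with an unknown-marker id so provenance is never silently lost.
Out-of-range vitals are interpreted against an age-banded threshold table
into derived findings (tachycardia, fever, hypoxia, ...) that then score
exactly like reported findings.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import EngineConfig
from .errors import ConfigurationError, EmptyCaseError, SchemaError
from .knowledge_base import KnowledgeBase, normalize_label

#: Prefix marking a reported label that resolved to no KB finding.
UNKNOWN_PREFIX = "unknown:"


def is_unknown(finding_id: str) -> bool:
    return finding_id.startswith(UNKNOWN_PREFIX)


class Demographics(BaseModel):
    model_config = ConfigDict(extra="forbid")

    age: float = Field(ge=0)  # years; fractional for infants
    sex: Literal["female", "male", "unknown"] = "unknown"


class CaseFinding(BaseModel):
    model_config = ConfigDict(extra="forbid")

    finding_id: str
    duration_hours: Optional[float] = Field(default=None, ge=0)
    reported_severity: Optional[int] = Field(default=None, ge=1, le=5)
    source: Literal["reported", "derived_from_vitals"] = "reported"


class VitalSigns(BaseModel):
    model_config = ConfigDict(extra="forbid")

    heart_rate: Optional[float] = Field(default=None, gt=0)
    respiratory_rate: Optional[float] = Field(default=None, gt=0)
    systolic_bp: Optional[float] = Field(default=None, gt=0)
    temperature: Optional[float] = Field(default=None, gt=0)
    spo2: Optional[float] = Field(default=None, gt=0, le=100)

    def present(self) -> dict[str, float]:
        return {
            k: v for k, v in self.model_dump().items() if v is not None
        }


class PatientCase(BaseModel):
    model_config = ConfigDict(extra="forbid")

    case_id: str
    demographics: Demographics
    findings: list[CaseFinding] = Field(min_length=1)
    vitals: VitalSigns = Field(default_factory=VitalSigns)

    @model_validator(mode="after")
    def _check(self) -> "PatientCase":
        if not any(not is_unknown(f.finding_id) for f in self.findings):
            raise ValueError("case has no findings resolvable in a KB")
        return self

    def known_finding_ids(self) -> list[str]:
        return [f.finding_id for f in self.findings if not is_unknown(f.finding_id)]

    def unknown_labels(self) -> list[str]:
        return [
            f.finding_id[len(UNKNOWN_PREFIX):]
            for f in self.findings
            if is_unknown(f.finding_id)
        ]

    def min_known_duration(self) -> Optional[float]:
        ds = [f.duration_hours for f in self.findings if f.duration_hours is not None]
        return min(ds) if ds else None


def normalize_finding(raw_label: str, kb: KnowledgeBase) -> str:
    """Resolve a free finding label to a KB finding id.

    Lookup is case-insensitive and whitespace/punctuation-insensitive over
    labels and synonyms.  A label with no match returns an unknown-marker id
    (``unknown:<normalized label>``) rather than being dropped.
    """
    norm = normalize_label(raw_label)
    return kb.label_index().get(norm, UNKNOWN_PREFIX + norm)


def interpret_vitals(
    vitals: VitalSigns,
    demographics: Demographics,
    config: EngineConfig,
    kb: Optional[KnowledgeBase] = None,
) -> list[CaseFinding]:
    """Derive one finding per out-of-range vital; in-range vitals yield nothing.

    The derived labels (tachycardia, bradypnea, fever, ...) come from the
    configured age-banded threshold table and are resolved against the KB
    when one is given.  A vital with no threshold row covering the patient's
    age is a configuration error.
    """
    out: list[CaseFinding] = []
    for vital, value in sorted(vitals.present().items()):
        rows = config.vital_thresholds.get(vital, [])
        row = next(
            (r for r in rows if r.age_lo <= demographics.age < r.age_hi), None
        )
        if row is None:
            raise ConfigurationError(
                f"no {vital} threshold row covers age {demographics.age}"
            )
        label: Optional[str] = None
        if row.low is not None and value < row.low:
            label = row.low_finding
        elif row.high is not None and value > row.high:
            label = row.high_finding
        if label is None:
            continue
        fid = normalize_finding(label, kb) if kb is not None else label
        out.append(CaseFinding(finding_id=fid, source="derived_from_vitals"))
    return out


# ---------------------------------------------------------------------------
# Parsing case files
# ---------------------------------------------------------------------------

_VITAL_COLUMNS = {
    "hr": "heart_rate",
    "rr": "respiratory_rate",
    "sbp": "systolic_bp",
    "temp": "temperature",
    "spo2": "spo2",
}


def parse_case(
    record: dict, kb: KnowledgeBase, config: EngineConfig | None = None
) -> PatientCase:
    """Build a :class:`PatientCase` from one JSON record or TSV row dict.

    Finding labels are normalized against the KB; vitals are interpreted and
    appended as derived findings.  Zero resolvable findings (after vitals
    interpretation) is an :class:`EmptyCaseError`.
    """
    cfg = config or EngineConfig()
    try:
        case_id = str(record["case_id"])
        demo = Demographics(
            age=float(record["age"]),
            sex=str(record.get("sex", "unknown")).strip().lower() or "unknown",
        )
    except (KeyError, TypeError, ValueError) as exc:
        field = exc.args[0] if isinstance(exc, KeyError) else "age/sex"
        raise SchemaError(f"malformed case record: field {field!r}: {exc}") from exc

    labels = record.get("findings", [])
    if isinstance(labels, str):
        labels = [s for s in (part.strip() for part in labels.split(";")) if s]
    duration = record.get("duration_hours")
    if duration is not None and not (isinstance(duration, float) and math.isnan(duration)):
        duration = float(duration)
    else:
        duration = None

    findings = [
        CaseFinding(finding_id=normalize_finding(lab, kb), duration_hours=duration)
        for lab in labels
    ]

    vitals_kwargs = {}
    for col, field in _VITAL_COLUMNS.items():
        v = record.get(col, record.get(field))
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            vitals_kwargs[field] = float(v)
    vitals = VitalSigns(**vitals_kwargs)
    findings.extend(interpret_vitals(vitals, demo, cfg, kb))

    if not any(not is_unknown(f.finding_id) for f in findings):
        raise EmptyCaseError(
            f"case {case_id!r}: no finding resolves in the KB "
            f"(labels: {labels or 'none'})"
        )
    return PatientCase(
        case_id=case_id, demographics=demo, findings=findings, vitals=vitals
    )


def load_cases(
    path: str | Path, kb: KnowledgeBase, config: EngineConfig | None = None
) -> list[PatientCase]:
    """Read a JSON list of case records or a TSV case table."""
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"case file not found: {p}")
    if p.suffix.lower() == ".json":
        records = json.loads(p.read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise SchemaError("case JSON must be a list of records")
    else:
        records = pd.read_csv(p, sep="\t").to_dict(orient="records")
    return [parse_case(r, kb, config) for r in records]
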