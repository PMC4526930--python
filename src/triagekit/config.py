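"""Run-time configuration for the triage engine.

All tunable constants of the scoring pipeline live in :class:`EngineConfig`:
the representative probability assigned to each curated frequency category,
the penalties for unmatched and missing-key findings, the differential cut
``top_k``, the mid-band rounding interval, the "short duration" threshold,
and the age-banded vital-sign reference ranges.  Defaults can be overridden
from a YAML or JSON file via :func:`load_config`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError

#: Closed vocabulary of curated finding-frequency categories, ordered from
#: most to least frequent.  'key' means required for the diagnosis.
FREQUENCY_CATEGORIES = ("key", "very_common", "common", "uncommon", "rare")

#: Representative probabilities: arithmetic midpoints of the curated ranges
#: (>50%, 10-50%, 1-10%, <1%).  'key' uses the very_common value; its
#: required-ness is enforced separately through the missing-key penalty.
DEFAULT_FREQUENCY_PROBABILITIES = {
    "key": 0.75,
    "very_common": 0.75,
    "common": 0.30,
    "uncommon": 0.055,
    "rare": 0.005,
}


class VitalThreshold(BaseModel):
    """Normal range for one vital sign within one age band."""

    age_lo: float = Field(ge=0)
    age_hi: float
    low: Optional[float] = None
    high: Optional[float] = None
    low_finding: Optional[str] = None
    high_finding: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "VitalThreshold":
        if self.age_hi <= self.age_lo:
            raise ValueError("age_hi must exceed age_lo")
        return self


def _default_vital_thresholds() -> dict[str, list[VitalThreshold]]:
    # Conventional textbook reference ranges, age-banded infant/child/adult.
    # Fully configurable: the one vitals-related scoring mismatch we guard
    # against is over-sensitivity to minor aberrance, so sites can retune.
    def rows(vital, bands):
        return [
            VitalThreshold(
                age_lo=lo, age_hi=hi, low=low, high=high,
                low_finding=lf, high_finding=hf,
            )
            for (lo, hi, low, high, lf, hf) in bands
        ]

    return {
        "heart_rate": rows("heart_rate", [
            (0, 1, 100, 160, "bradycardia", "tachycardia"),
            (1, 12, 70, 120, "bradycardia", "tachycardia"),
            (12, 120, 60, 100, "bradycardia", "tachycardia"),
        ]),
        "respiratory_rate": rows("respiratory_rate", [
            (0, 1, 30, 60, "bradypnea", "tachypnea"),
            (1, 12, 18, 30, "bradypnea", "tachypnea"),
            (12, 120, 12, 20, "bradypnea", "tachypnea"),
        ]),
        "systolic_bp": rows("systolic_bp", [
            (0, 1, 70, 180, "hypotension", "hypertension"),
            (1, 12, 80, 180, "hypotension", "hypertension"),
            (12, 120, 90, 180, "hypotension", "hypertension"),
        ]),
        "temperature": rows("temperature", [
            (0, 120, 36.0, 38.0, "hypothermia", "fever"),
        ]),
        "spo2": rows("spo2", [
            (0, 120, 92.0, None, "hypoxia", None),
        ]),
    }


class EngineConfig(BaseModel):
    """All tunable parameters of the scoring and rounding pipeline."""

    frequency_probabilities: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_PROBABILITIES)
    )
    #: Likelihood multiplier for a case finding with no curated association.
    unmatched_finding_epsilon: float = 0.001
    #: Multiplicative penalty per 'key' finding absent from the presentation.
    key_missing_penalty: float = 0.05
    #: Differential cut: number of top diagnoses averaged into the score.
    top_k: int = 100
    #: Closed fractional band that triggers the context-dependent rounding.
    rounding_band: tuple[float, float] = (0.40, 0.60)
    #: Symptom durations below this many hours count as "short".
    short_duration_hours: float = 48.0
    #: A diagnosis is urgent/emergent (critical-test trigger eligible) when
    #: the severe end of its severity range is at or below this level.
    urgent_severity_cutoff: int = 2
    #: Hard-override findings forcing severity 1 (off by default).
    revive_override_findings: list[str] = Field(default_factory=list)
    vital_thresholds: dict[str, list[VitalThreshold]] = Field(
        default_factory=_default_vital_thresholds
    )
    strict: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EngineConfig":
        lo, hi = self.rounding_band
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("rounding_band must satisfy 0 < lo <= hi < 1")
        missing = set(FREQUENCY_CATEGORIES) - set(self.frequency_probabilities)
        if missing:
            raise ValueError(f"frequency_probabilities missing {sorted(missing)}")
        for cat, p in self.frequency_probabilities.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"probability for {cat!r} must lie in (0, 1]")
        if not (0.0 < self.unmatched_finding_epsilon <= 1.0):
            raise ValueError("unmatched_finding_epsilon must lie in (0, 1]")
        if not (0.0 < self.key_missing_penalty <= 1.0):
            raise ValueError("key_missing_penalty must lie in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        return self


def load_config(path: str | Path | None = None, **overrides) -> EngineConfig:
    """Build an :class:`EngineConfig` from defaults <- file <- overrides."""
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        text = p.read_text(encoding="utf-8")
        data = (json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file must hold a mapping: {p}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return EngineConfig(**data)
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
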