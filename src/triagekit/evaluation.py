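"""Ordinal agreement between two 5-level triage raters.

Implements the chance-corrected weighted kappa statistic for a k x k
confusion matrix with agreement weights

    linear:     w_ij = 1 - |i-j| / (k-1)
    quadratic:  w_ij = 1 - (i-j)^2 / (k-1)^2
    unweighted: w_ij = 1 if i == j else 0

po is the weighted observed agreement, pe the weighted agreement expected
from the marginals under independence, and kappa = (po - pe) / (1 - pe).
The number of ordinal categories is fixed at k = 5 by the triage scale
itself, not by the categories observed: a subgroup with empty columns keeps
the full 5-level distance geometry.  Confidence intervals come from a
seeded case-level percentile bootstrap.  Interpretation bands follow the
standard cut-points (< 0 none, 0-0.20 slight, 0.21-0.40 fair, 0.41-0.60
moderate, 0.61-0.80 substantial, 0.81-1.0 almost perfect).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import SchemaError, UndefinedKappaError

Scheme = Literal["linear", "quadratic", "unweighted"]

#: (upper edge inclusive, label) — lower edges are the previous band's upper.
_BANDS = [
    (0.0, "no agreement"),      # kappa < 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]


class ScorePair(BaseModel):
    model_config = ConfigDict(extra="forbid")

    case_id: str
    rater_a: int = Field(ge=1, le=5)  # engine
    rater_b: int = Field(ge=1, le=5)  # reference standard (e.g. ESI)


class ConfusionMatrix(BaseModel):
    """5x5 cross-tabulation; rows = engine level, columns = reference level."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    counts: list[list[int]]
    k: int = 5

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def n(self) -> int:
        return int(self.array.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.array))

    def to_pairs(self) -> list[ScorePair]:
        """Expand cells back into individual score pairs (synthetic ids)."""
        pairs = []
        m = self.array
        for i in range(self.k):
            for j in range(self.k):
                for r in range(m[i, j]):
                    pairs.append(
                        ScorePair(
                            case_id=f"cell{i + 1}{j + 1}_{r + 1}",
                            rater_a=i + 1,
                            rater_b=j + 1,
                        )
                    )
        return pairs


class KappaResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kappa: float = Field(le=1.0)
    scheme: Scheme
    po_weighted: float = Field(ge=0.0, le=1.0)
    pe_weighted: float = Field(ge=0.0, le=1.0)
    ci: Optional[tuple[float, float]] = None
    ci_method: Literal["bootstrap", "none"] = "none"
    band: str = ""


def build_confusion(pairs: Sequence[ScorePair], k: int = 5) -> ConfusionMatrix:
    """Cross-tabulate paired scores; empty input violates n >= 1."""
    if not pairs:
        raise SchemaError("cannot build a confusion matrix from zero pairs")
    counts = np.zeros((k, k), dtype=np.int64)
    for p in pairs:
        if not (1 <= p.rater_a <= k and 1 <= p.rater_b <= k):
            raise SchemaError(
                f"case {p.case_id!r}: score outside 1..{k}"
            )
        counts[p.rater_a - 1, p.rater_b - 1] += 1
    return ConfusionMatrix(counts=counts.tolist(), k=k)


def kappa_weights(k: int, scheme: Scheme) -> np.ndarray:
    i = np.arange(k)[:, None]
    j = np.arange(k)[None, :]
    if scheme == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if scheme == "quadratic":
        return 1.0 - (i - j) ** 2 / (k - 1) ** 2
    if scheme == "unweighted":
        return (i == j).astype(float)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(matrix: ConfusionMatrix, scheme: Scheme = "linear") -> KappaResult:
    """Chance-corrected weighted agreement for one confusion matrix."""
    m = matrix.array.astype(float)
    n = m.sum()
    if n < 1:
        raise SchemaError("confusion matrix is empty")
    w = kappa_weights(matrix.k, scheme)
    po = float((w * m).sum() / n)
    pe = float((w * np.outer(m.sum(axis=1), m.sum(axis=0))).sum() / n**2)
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "expected agreement is 1 (all mass in one category for both "
            "raters); kappa is undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(
        kappa=kappa,
        scheme=scheme,
        po_weighted=po,
        pe_weighted=pe,
        band=interpret_kappa(kappa),
    )


def kappa_bootstrap_ci(
    pairs: Sequence[ScorePair],
    scheme: Scheme = "linear",
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for kappa over case-level resamples.

    Deterministic given the seed.  Resamples with undefined kappa are
    skipped and counted; more than 1% skipped emits a warning.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    a = np.array([p.rater_a for p in pairs], dtype=np.int64)
    b = np.array([p.rater_b for p in pairs], dtype=np.int64)
    n = len(a)
    if n == 0:
        raise SchemaError("cannot bootstrap zero pairs")
    k = 5
    w = kappa_weights(k, scheme)
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    skipped = 0
    kept = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        m = np.zeros((k, k))
        np.add.at(m, (a[idx] - 1, b[idx] - 1), 1.0)
        po = (w * m).sum() / n
        pe = (w * np.outer(m.sum(axis=1), m.sum(axis=0))).sum() / n**2
        if pe >= 1.0 - 1e-15:
            skipped += 1
            continue
        stats[kept] = (po - pe) / (1.0 - pe)
        kept += 1
    if kept == 0:
        raise UndefinedKappaError(
            "every bootstrap resample had undefined kappa (degenerate pairs)"
        )
    if skipped > 0.01 * B:
        warnings.warn(
            f"{skipped}/{B} bootstrap resamples had undefined kappa and were "
            "skipped",
            stacklevel=2,
        )
    lo, hi = np.percentile(stats[:kept], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def match_fraction(matrix: ConfusionMatrix) -> float:
    """Fraction of exact (diagonal) agreements."""
    if matrix.n < 1:
        raise SchemaError("confusion matrix is empty")
    return matrix.trace / matrix.n


def subgroup_matrix(
    pairs: Sequence[ScorePair], reference_levels: Iterable[int], k: int = 5
) -> ConfusionMatrix:
    """Confusion matrix restricted to pairs whose reference score is in the
    given levels; the full k x k shape (and ordinal geometry) is retained."""
    levels = set(reference_levels)
    if not levels:
        raise SchemaError("reference_levels must be non-empty")
    kept = [p for p in pairs if p.rater_b in levels]
    return build_confusion(kept, k=k)


def interpret_kappa(kappa: float) -> str:
    """Agreement band label for a kappa value (boundaries close the lower
    band's upper edge: 0.20 is still 'slight', 0.40 'fair', ...)."""
    if kappa > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0.0:
        return _BANDS[0][1]
    for upper, label in _BANDS[1:]:
        if kappa <= upper:
            return label
    return _BANDS[-1][1]


# ---------------------------------------------------------------------------
# Report and file I/O
# ---------------------------------------------------------------------------

def load_pairs(path: str | Path) -> list[ScorePair]:
    """CSV with columns case_id, engine_score, reference_score."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"case_id", "engine_score", "reference_score"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"pairs file must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return [
        ScorePair(
            case_id=str(r.case_id),
            rater_a=int(r.engine_score),
            rater_b=int(r.reference_score),
        )
        for r in df.itertuples()
    ]


def load_matrix(path: str | Path, k: int = 5) -> ConfusionMatrix:
    """k x k CSV of integer counts, row = engine level (no header)."""
    import pandas as pd

    df = pd.read_csv(path, header=None)
    if df.shape != (k, k):
        raise SchemaError(f"matrix file must be {k}x{k}, found {df.shape}")
    return ConfusionMatrix(counts=df.to_numpy(dtype=np.int64).tolist(), k=k)


def agreement_report(
    matrix: ConfusionMatrix,
    pairs: Optional[Sequence[ScorePair]] = None,
    subgroup_levels: Iterable[int] = (1, 2),
    boot_B: int = 0,
    seed: int = 0,
) -> dict:
    """Full agreement summary: n, matched, match fraction, kappa under both
    ordinal schemes (with bootstrap CIs when pairs and B are given), and the
    same block for the high-acuity reference subgroup."""
    if pairs is None:
        pairs = matrix.to_pairs()

    def block(m: ConfusionMatrix, ps: Sequence[ScorePair]) -> dict:
        out = {
            "n": m.n,
            "matched": m.trace,
            "match_fraction": match_fraction(m),
            "kappa": {},
        }
        for scheme in ("linear", "quadratic"):
            res = weighted_kappa(m, scheme)
            entry = {
                "kappa": res.kappa,
                "po": res.po_weighted,
                "pe": res.pe_weighted,
                "band": res.band,
            }
            if boot_B and ps:
                entry["ci95"] = kappa_bootstrap_ci(ps, scheme, B=boot_B, seed=seed)
            out["kappa"][scheme] = entry
        return out

    sub_pairs = [p for p in pairs if p.rater_b in set(subgroup_levels)]
    report = {"overall": block(matrix, pairs)}
    if sub_pairs:
        report["subgroup"] = {
            "reference_levels": sorted(set(subgroup_levels)),
            **block(subgroup_matrix(pairs, subgroup_levels, matrix.k), sub_pairs),
        }
    return report
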