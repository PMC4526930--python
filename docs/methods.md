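# Methods

## The severity engine

The engine models triage as inference over a bipartite diagnosis–finding
graph followed by ordinal aggregation.

**Scoring model.** The association between a diagnosis and a finding
carries a curated frequency category rather than a numeric probability.
Categories map to representative probabilities — the arithmetic midpoints
of their defining ranges — by default:

| category    | defining range | default probability |
|-------------|----------------|---------------------|
| key         | required       | 0.75 (as very common) |
| very common | > 50%          | 0.75 |
| common      | 10–50%         | 0.30 |
| uncommon    | 1–10%          | 0.055 |
| rare        | < 1%           | 0.005 |

The per-diagnosis score is the product of the baseline prevalence and the
per-finding likelihoods, treating findings as conditionally independent
given the diagnosis. This naive-Bayes form is the simplest model consistent
with a probabilistic graphical structure; it is a declared design choice,
not the only "combined" weighting one could defend. Two soft constants
complete it, both configurable:

- `unmatched_finding_epsilon` (ε, default 0.001): likelihood of a case
  finding the diagnosis has no association with. Because ε is uniform
  across diagnoses, a finding unknown to every diagnosis rescales all
  scores equally and leaves the ranking and weights unchanged.
- `key_missing_penalty` (π, default 0.05): multiplicative penalty per
  "key" (required) finding absent from the case. A hard zero would make a
  single missed entry fatal; the soft penalty keeps the diagnosis rankable
  while demoting it strongly. How required findings should behave when
  absent is genuinely open; this is our resolution.

Findings merely not mentioned (other than key ones) contribute nothing: an
open-world assumption, with no negation model.

**Demographic modulation.** Edges accept multiplicative modifiers on
half-open age bands `[lo, hi)` crossed with sex, e.g. a U-shaped age effect
(×2.0 for the very young and the very old, ×0.5 in between). The modified
likelihood is clamped to ≤ 1. The underlying "multi-dimensional probability
distribution" of the curation model is unspecified; banded multiplicative
modifiers are this package's explicit, auditable form. Race and
symptom-duration modifier fields are accepted in the schema but inactive by
default, since no functional form is defined for them.

**Per-diagnosis case severity.** Each association also carries the integer
severity (1 = most severe) the finding implies for that diagnosis. A
diagnosis's case severity is the minimum (most severe) such value over the
case's matched findings, clamped into the diagnosis's curated severity
range; with no informative match it falls back to the rounded midpoint of
the range, an exact half rounding toward the severe end. Whether per-case
severity should depend on findings at all (rather than being a fixed
attribute) is not settled; the clamped-minimum rule is our choice, erring
severe.

**Aggregation and rounding.** The fractional severity is the
differential-weighted mean of case severities over the top K = 100
diagnoses. A fractional part inside the closed band [0.40, 0.60] is
resolved by context: presence of a critical-test recommendation on an
urgent/emergent differential entry (base severity ≤ 2; the cutoff is
configurable) or a minimum known symptom duration under 48 h escalates to
the numerically smaller (more severe) level; otherwise the score
de-escalates. "Short duration" is never quantified by the source
methodology; 48 h is a conventional default and configurable. Band
endpoints are inclusive, with a 1e-9 tolerance so that values like 3.6
(whose fractional part is 0.6000000000000001 in binary floating point)
stay inside the band. Outside the band, nearest-integer rounding applies;
the default band contains .5, so no half-way tie can arise there.

**Vital signs.** Out-of-range vitals are interpreted against an age-banded
(infant < 1 y, child 1–12 y, adult ≥ 12 y) table of conventional textbook
reference ranges into derived findings (tachycardia, bradypnea, fever,
hypoxia, ...) that score exactly like reported findings. The table is fully
configurable because over-sensitive vital interpretation is a known failure
mode of this class of engine. A hard-override hook (a configured finding
forcing level 1) exists but is off by default.

**Determinism.** Ties in raw score break by higher baseline prevalence,
then lexicographic id; all randomness is seeded; CLI numbers print with
fixed 3-decimal half-away-from-zero rounding. Identical inputs give
byte-identical outputs.

## The agreement harness

Weighted Cohen's kappa on the 5×5 confusion matrix, with the category count
fixed at k = 5 by the triage scale, not by the observed data: a subgroup
with empty columns keeps the full ordinal distance geometry (this retention
is what makes the high-acuity subgroup value 0.851 reproducible).
Interpretation bands: < 0 no agreement, 0–0.20 slight, 0.21–0.40 fair,
0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–1.0 almost perfect;
interior boundaries belong to the lower band.

**Linear vs quadratic.** Both schemes are first-class and the report prints
both. On the packaged 73-case matrix the linear scheme
(w = 1 − |i−j|/4) yields 0.933 and the quadratic scheme 0.947; on the
41-case high-acuity subgroup the linear scheme yields 0.851. The published
headline values (0.933, 0.851) are therefore reproduced by the *linear*
formula even though the statistic is described as quadratic in its source;
the package reports the linear value as the headline and the quadratic
value alongside rather than silently picking one. Similarly, the subgroup's
published exact-match percentage (94.7%) differs slightly from 39/41 ≈
95.1%; the matched count 39 is treated as authoritative.

**Confidence intervals.** Case-level percentile bootstrap (default B =
2000, seeded, α = 0.05). The original interval's upper bound for the
subgroup exceeds 1, suggesting a normal-approximation method; since that
method is unknown, exact CI reproduction is not attempted — the bootstrap
interval is required only to contain the point estimate and be stable in B.
Degenerate resamples (all mass in one cell for both raters) are skipped and
counted, with a warning above 1%.

## The synthetic generator

No real curated database or vignette set is redistributable, so tests run
on synthetic stand-ins sharing the statistical structure the engine
assumes. Generator defaults, fixed once:

- association categories drawn from (very common 0.20, common 0.40,
  uncommon 0.30, rare 0.08, key 0.02) — chosen to exercise every scoring
  branch, including the rare required-finding edge;
- baseline prevalence log-uniform on [1e-4, 1e-1];
- severity ranges: severe end from a configurable mix (uniform by
  default), mild end extending it by 0–2 levels;
- critical test attached with probability 0.8 to diagnoses with base
  severity ≤ 2;
- cases: true diagnosis drawn ∝ prevalence; each associated finding
  included with its category probability × demographic multiplier, then
  dropped with the dropout rate (default 0.1); Poisson(0.05) spurious
  unassociated findings; ages Uniform(0, 90), sexes balanced, finding
  durations Exponential(mean 48 h); resampling guarantees ≥ 1 finding.

The resample guarantee conditions presentations on being non-empty, which
biases per-finding inclusion frequencies upward for sparsely connected
diagnoses; the calibration test therefore uses a densely connected KB
where the bias is negligible.

Because generator and engine share the likelihood model, recovery must be
high; the guards (true diagnosis in the top-10 differential for ≥ 80% of
500 seeded cases; mean absolute severity error ≤ 0.5) are engineering
regression thresholds, not clinical claims. Passing them shows the pipeline
is self-consistent — it says nothing about performance on real
presentations, where findings are correlated, negation matters, and the
knowledge base is imperfect.

## Problem sizes

The default test run uses small graphs (≤ 20 diagnoses, ≤ 120 findings),
500-case recovery runs, 200-matrix kappa oracle sweeps and B ≤ 4000
bootstrap resamples; these sizes make the suite and the acceptance script
complete in seconds while keeping Monte-Carlo noise well below the asserted
tolerances.

## Known limitations

- Free-text/NLP entry, EHR/FHIR integration, test-cost estimation and
  resource-need prediction are out of scope; finding entry is exact
  label/synonym lookup.
- The product score ignores finding–finding correlation; strongly
  co-occurring findings are over-counted.
- The reference scores consumed by the harness are taken as given; the
  harness measures agreement, not correctness of either rater.
- Multi-rater (> 2) agreement and ROC-style analyses are not provided.
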