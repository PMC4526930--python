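# triagekit

A 5-level emergency-triage severity engine driven by a curated
diagnosis–finding knowledge graph, together with the ordinal-agreement
harness needed to validate any triage scorer against a 5-level reference
standard such as the Emergency Severity Index (ESI).

**Who it is for.** Clinical-informatics researchers building or evaluating
computerized triage decision support: the engine turns a structured patient
presentation (demographics, findings, vital signs) into an integer acuity
level 1–5 (1 = immediate lifesaving intervention, 5 = no resources
expected), and the harness quantifies how well any two 5-level raters agree.

## The model

**Differential ranking.** Given a knowledge base of diagnoses *d* (with
baseline prevalence *P(d)* and a curated severity range) and findings *f*
connected by associations carrying a frequency category
(key / very common / common / uncommon / rare) and demographic modifiers,
each diagnosis is scored for a case with findings *F* by a
naive-Bayes-style product

```
score(d) = P(d) · ∏_{f ∈ F} L(f | d, demographics) · π^{#missing key findings}
```

where `L = min(1, p_category · demographic multiplier)` for associated
findings (p_category is the midpoint of the category's curated frequency
range, e.g. 0.75 for "very common"), `L = ε` (default 0.001) for findings
the diagnosis is not associated with, and `π` (default 0.05) penalizes each
"key" (required) finding the case lacks. The top K = 100 diagnoses,
renormalized to weights `w_d`, form the differential.

**Severity aggregation.** Each top-K diagnosis contributes an integer case
severity `s_d` (the most severe matched finding severity, clamped into the
diagnosis's range); the fractional acuity is the weighted mean
`S = Σ w_d · s_d ∈ [1, 5]`.

**Mid-band rounding.** A fractional part in the closed band [0.40, 0.60] is
ambiguous: if the differential contains an urgent/emergent diagnosis (base
severity ≤ 2) with a recommended critical test, or the symptoms are of short
duration (< 48 h), `S` rounds toward the more severe level (numerically
smaller); otherwise toward the less severe level. Fractions outside the
band round to the nearest integer.

**Agreement harness.** For a 5×5 confusion matrix of engine level *i* vs
reference level *j*, the weighted Cohen kappa is

```
κ = (p_o − p_e) / (1 − p_e),   p_o = Σ w_ij n_ij / n,   p_e = Σ w_ij r_i c_j / n²
```

with linear weights `w_ij = 1 − |i−j|/4` or quadratic
`w_ij = 1 − (i−j)²/16`, always over the full five ordinal categories.
Percentile-bootstrap confidence intervals and high-acuity subgroup analysis
(reference levels 1–2) are included.

## Worked example

The packaged 73-vignette confusion matrix (engine vs ESI reference):

```
$ triage kappa --fixture table5 --scheme linear
n	73
matched	69
match_fraction	0.945
kappa_linear	0.933
band	almost perfect
```

69 of 73 cases (95%) match exactly and the linear-weighted kappa of 0.933
lies in the "almost perfect" agreement band (> 0.80). Simulating a small
knowledge base and scoring synthetic cases end to end:

```
$ triage --seed 7 simulate kb --out demo --n-diagnoses 8 --n-findings 20 --assoc-per-diagnosis 3
$ triage --seed 8 simulate cases --out demo --kb demo/kb.json --n-cases 3
$ triage score --kb demo/kb.json --cases demo/cases.json
case_id	fractional	final	trigger
case00000	4.983	5	none
case00001	2.016	2	none
case00002	2.893	3	none
```

Each row is one case: the weighted-mean fractional severity, the rounded
1–5 level, and which rounding rule fired (`none` means the fraction was
outside the ambiguous mid band).

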