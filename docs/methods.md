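# Methods

This note records the model, the fixed parameters, the interpretation
choices made where the clinical rules leave room, and what the synthetic
generator does and does not emulate.

## Data model and episode linkage

A patient record is a typed bundle (pydantic models in
`cardioevent.ehr_model`) of hospitalizations with position-ordered
discharge diagnoses, labs with per-result upper limits of normal (ULN),
coded ECG interpretation statements, echocardiograms, outpatient claims,
and an enrollment start date. All clinical events must fall on or after
enrollment; diagnosis positions must be contiguous from 1 (position 1 is
the primary discharge diagnosis).

An **episode of care** is a hospitalization whose *discharge date* falls
inside the surveillance period, together with every lab, ECG and echo
timestamped within a linkage window of the stay:

- linkage window: **24 hours** before admission through **24 hours** after
  discharge, boundaries inclusive. The pad captures emergency-department
  results filed just before formal admission and read-outs finalized just
  after discharge.
- observation time is computed in **365.25-day years**; the ambulatory
  criteria require **≥ 2.0 years** of observation before the first
  heart-disease diagnosis.

## Code matching

Diagnosis codes are matched declaratively (`cardioevent.codesets`) with
four spec kinds:

- **EXACT** — string identity after uppercasing.
- **PREFIX** — match at a code boundary: `410.7` matches `410.7` and
  `410.71`, never `410.75X`-style accidental substrings of unrelated
  rubrics; alphabetic suffixes (interface-terminology children such as
  `410.90CP`) only match when the spec's system is IMO.
- **RUBRIC_RANGE** — numeric interval over ICD-9 rubrics. A candidate code
  is truncated to the decimal precision of the endpoints before
  comparison, so `410.91` falls in `410.9–410.9`; a code with *fewer*
  decimals than the endpoints (bare `410` against `410.0–410.6`) does not
  match, because it does not assert the finer digit.
- **PREFIX_EXCEPT** — a prefix minus enumerated children
  (`410.91 except 410.91D`).

Every built-in set is tested against brute-force string enumeration over
the complete 410–429 and 786.5 code space.

## The three algorithm generations

Classification (`cardioevent.phenotyper`) evaluates each generation's
criteria in a fixed clinical-priority order and returns the first match;
the rationale lists *every* criterion that fired, so overlap is auditable.
Patients matching nothing are `UNCLASSIFIED`.

Fixed thresholds (all configurable in `AlgorithmConfig`, defaults are the
study conditions):

| parameter | default | note |
|---|---|---|
| troponin multiplier, generation 1 | 1.0 × ULN | strictly greater-than |
| troponin multiplier, generations 2–3 | 3.0 × ULN | strictly greater-than; exactly 3× does not qualify |
| BNP | > ULN | strictly greater-than |
| EF threshold | 35 % | **inclusive** (EF = 35 qualifies); applied in generations 2–3 only |
| ST-elevation ECG statement codes | 964–968 inclusive | 963 and 969 do not qualify |
| minimum observation | 2.0 years | 365.25-day years |
| ambulatory lab window (generation 1) | ± 30 days | around the first heart-disease diagnosis |

Interpretation choices where the rules underdetermine behavior (also in
the project decision log):

- **Generation-2 ambulatory** requires the *first* heart-disease claim to
  be an office visit *and* to fall within the surveillance period. Without
  the in-period requirement the criterion would also capture every
  prevalent (chronic) patient whose disease began with an office visit
  years earlier, and would shadow the chronic category entirely by row
  order; the criterion is read as identifying incident ambulatory
  presentations.
- **Generation-3 ambulatory/chronic** requires a heart-disease diagnosis
  at any time and *no non-elective* heart-disease hospitalization
  overlapping the period; an elective admission does not disqualify.
- Hospitalization overlap (any intersection with the period) is used for
  the negative "no hospitalization during the period" clauses, which is
  broader than the discharge-date rule that defines scored episodes — a
  stay straddling the period boundary should disqualify an "ambulatory"
  call even if it is not itself a scored episode.

## Agreement statistics

`cardioevent.agreement` computes, from aligned algorithm/reviewer label
maps: the confusion matrix (algorithm on rows, reviewers on columns),
observed agreement p_o, chance agreement p_e from the marginals, Cohen's
κ = (p_o − p_e)/(1 − p_e), and a normal-approximation 95% CI truncated to
[−1, 1]. Two standard errors are offered:

- `cohen` (default): sqrt( p_o (1 − p_o) / (n (1 − p_e)²) ) — Cohen's
  original large-sample SE, the conventional choice for reporting.
- `fleiss`: the Fleiss–Cohen–Everitt asymptotic variance, cross-checked
  in the tests against `statsmodels`.

Per-category agreement defaults to the **algorithm-row** basis: of the
cases the algorithm assigned to a category, the fraction the reviewers
confirmed. κ is implemented in-package (it is the scientific core), but
tested against exact `fractions.Fraction` summation, `statsmodels`, and
`scikit-learn` as independent oracles.

Degenerate inputs: if p_e = 1 (all mass in one cell) κ is defined as 1.0
when p_o = 1; a matrix needs at least two labels and n ≥ 1.

## Synthetic cohort generator

`cardioevent.synthetic` builds records that *provably* satisfy their
target category: every generated patient is re-classified on the spot and
generation fails loudly rather than emit an unsound record. Quantities
near thresholds are jittered safely interior to them — troponin ratio in
(3.5, 20] × ULN for positives and (0.1, 0.9] for negatives, BNP in
(1.5, 10] × ULN, depressed EF in [15, 35] % — so small numeric
perturbations cannot flip a label.

**Discordant records** (algorithm label ≠ reviewer label) are built two
ways. If the algorithm label outranks the reviewer label in the
hierarchy, the reviewer-label scenario is decorated with the
higher-priority trigger. Otherwise the algorithm-label scenario is
decorated with *soft* reviewer-side evidence (e.g., for a reviewer-HF
case: a secondary 428 code, elevated BNP, EF 28%) and any decoration that
would flip the algorithm's label is reverted. The canonical
generation-3 disagreement — a heart-failure admission the algorithm calls
nSTEMI — is realized with an nSTEMI interface term in diagnosis position
1 and the 428 code demoted to position 2, since the heart-failure
criterion requires the primary position.

Determinism: each patient draws from an independent
`numpy.random.default_rng([seed, counter])` substream, so cohorts are
byte-identical across runs and insertion order cannot leak randomness
between patients.

**Negative controls** are near-miss records one notch outside each
threshold (EF 36%, troponin exactly 3× ULN, ECG statement 963,
observation 1.9 years, a pacemaker procedure against unstable angina, a
bare ICD-9 410.92 against the generation-3 MI sets).

What the generator does **not** emulate: real code-frequency
distributions, comorbidity structure, inter-reviewer disagreement beyond
the injected discordance counts, missing or contradictory data, or
free-text anything — it is a correctness harness for the classifier and
the agreement machinery, not an epidemiological simulator.

## Problem sizes used in verification

The validation-study reconstructions use the published per-category
concordance counts: generation 1, 60/64 confirmed merged infarctions;
generation 2, per-category concordances 16/24, 21/21, 39/50, 19/50,
23/50, 45/50 (overall 163/245 = 67%); generation 3, a 184-case cohort
(50 STEMI, 49 nSTEMI + 1 discordant, 34 HF, 50 ambulatory/chronic) giving
p_o = 183/184 = 99.46%, κ = 0.9927, 95% CI (0.9784, 1.00 after
truncation). Round-trip soundness is exercised over 100 seeds per
category × generation in the tests and 25 per pair (450 checks) in
`scripts/acceptance.py`.

## Limitations

- ICD-9-CM / IMO era only; no ICD-10 mapping.
- Single-period classification; no longitudinal event sequences.
- The generation-2 ambulatory reading above is one defensible resolution
  of an ambiguous rule; sites applying the rule differently should adjust
  `phenotyper._v2_ambulatory`.
- The asymptotic κ CI is a large-sample approximation; for very small n
  a bootstrap would be preferable.
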