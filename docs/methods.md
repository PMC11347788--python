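# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Observation model

Patient findings are typed observations — dichotomous (`yes`/`no`), nominal
(closed value list), or numeric (with a declared unit) — arranged in a forest
keyed by dotted identifiers (`2.2.1` is subordinate to `2.2`). Free text is
deliberately unsupported. `parent_id` is authoritative for the hierarchy; the
dotted-prefix relationship is *validated* rather than inferred, so renumbering
mistakes surface as loader errors instead of silent re-parenting.

Subordinate observations carry an **activation predicate** on the parent's
value. `always` marks purely organisational levels; the default for clinical
gates is "parent answered `yes`". Nominal or numeric parents must declare an
explicit predicate — there is no universal notion of a "positive" nominal
finding, so guessing one would be worse than requiring it.

Three resolution states follow for any observation:

- **active** — every gate on the ancestor chain is answered and satisfied;
  the engine reads the stored answer (or *unknown* if unanswered);
- **pending** — some gate is not yet answered; the value is *unknown* and the
  mandatory-field machinery points at the first unanswered gate, not at the
  subordinate leaf (you cannot sensibly ask for `2.2.3` before `2.2`);
- **closed** — some gate is answered so its predicate definitively fails. A
  closed *dichotomous* finding resolves to `no`: "no cardiac risk factors
  present" entails each individual risk factor being absent. Closed nominal
  and numeric observations stay *unknown*, since absence has no canonical
  value there; rules over such observations should test the gate explicitly.

The closed-resolves-to-no rule is a deliberate design choice. Without it, a
rule referencing a gated finding behind a negatively answered screen could
remain permanently undecidable while the mandatory set is empty — an
inconsistent state. With it, screening answers decide rules the way a
clinician reading the form would. Stored answers on non-active observations
are never read (and `set_answer` clears a subtree whenever a new answer
deactivates it), so evaluation is invariant to stale values.

**Missing is explicit.** An answer can be recorded as "asked but unknown",
distinct from "not yet asked"; both resolve to *unknown* in evaluation but
validators treat them differently (an explicit missing is valid data).

## Rule engine

Rules are data, never code: a rule has an action from a controlled vocabulary
(`ECG`, `echocardiography`, `cardiac_stress_test`, `chest_xray`,
`pulmonary_function`, `carotid_doppler`, `laboratory:<analyte>`,
`other:<measure>`), a guideline source tag, and one or more trigger
conditions, each a boolean expression (`all_of`/`any_of`/`not`/`atom`) or a
dichotomous decision tree (`if/then/else`), graded `1A…2C` or `none`.
Predicates only compare an observation or a named score against a literal;
derived quantities must be declared scores. This keeps every rule set
amenable to exhaustive truth-table checking, which the test suite exploits as
an independent oracle.

Evaluation is **Kleene three-valued**: *unknown* propagates unless
short-circuited (`any_of` with a true child is true; `all_of` with a false
child is false; a tree stops at the first unanswered branch predicate). A
rule fires when at least one condition is definitely true. If any rule's
status is still *unknown*, evaluation raises an error naming the blocking
observations — the mandatory-field mechanism forces completeness rather than
guessing. The mandatory set contains only observations that can still change
a rule's status: atoms inside an already-false `all_of` or already-true
`any_of` are not demanded.

Display follows the GRADE ordering `1A > 1B > 1C > 2A > 2B > 2C > none`: any
strong (1) recommendation outranks any weak (2) one regardless of evidence
letter; ties are broken by declaration order. All fired conditions remain in
the output; exactly one is marked displayed.

**Clearance** is the primary decision: cleared iff no fired rule's action is
an examination. `laboratory:*` actions are examinations; `other:*` actions
(consults, medication changes) are measures and do not block clearance.
Output ordering is deterministic — (displayed grade, rule id) — so identical
inputs give byte-identical reports.

The shipped rule pack is a **demonstrator**. The cardiac stress-test rule is
a faithful encoding of the published AND/OR example (poor functional capacity
by any of three MET observations, ≥ 3 clinical cardiac risk factors, and
high-risk surgical conditions; the ≥ 3 threshold is a rule-file parameter).
The ECG decision tree's exact branch predicates are not published; the
shipped tree (risk-factor count × surgical risk class, with a weaker
age-based condition to exercise GRADE display) is labelled as a demonstrator
encoding, as are the remaining examination rules. No claim is made that the
pack reconstructs any guideline corpus.

Rule files are validated strictly — unknown keys are rejected — by a
hand-written validator; `data/rule_schema.json` is the normative format
description (the environment provides no JSON-Schema library, so the schema
document is documentation plus a cross-check, not the validator itself).

## Risk scores

Every score is (weighted) counting over a data file:

- **RCRI clinical factors** — count of five dichotomous findings
  (ischaemic heart disease, heart failure, cerebrovascular disease,
  insulin-treated diabetes, creatinine > 2.0 mg/dL); `rcri_total` adds the
  high-risk-surgery item. Rules must name which form they use.
- **Charlson** — weighted sum (weights 1/2/3/6) over the classic 19-row
  condition table; severity pairs (diabetes ± end-organ damage, mild vs
  moderate/severe liver disease) are linked so only the severe form counts
  when both are flagged, i.e. 17 independent conditions. Any unresolved flag
  makes the score unknown, matching the explicit "Unknown" stratum such
  cohorts report.
- **STOP-BANG** — eight one-point items, four from observations and four
  derived from record fields (BMI > 35, age > 50, neck circumference flag,
  male sex); the default high-risk cutoff of ≥ 3 is table data.
- **POSPOM-style mortality points** — additive age-band + comorbidity +
  procedure-group points. The published table is not redistributable here, so
  the shipped table `pospom_points_synthetic.yaml` is a **synthetic stand-in**
  with the real structure but demonstrator values; it is loaded with SHA-256
  checksum verification and its outputs must never be compared against
  published score values. Swapping in a faithful transcription is a pure data
  change.
- **AKI risk index** — count of preoperative risk factors mapped to classes
  I–V (≤2, 3, 4, 5, ≥6); the factor list mixes observation flags and record
  fields and is configurable data.

Invariants tested: each score is monotone in its items, stays in its declared
range, and is invariant to permutations of its table rows.

## Agreement statistics

For cells `(a, b, c, d)` (both clear / approach-only clear / reference-only
clear / both reject), `N = a+b+c+d`:

- `p_o = (a+d)/N`.
- **Cohen's κ**: `p_e = (p_1 q_1 + p_2 q_2)` from the marginal proportions;
  `κ = (p_o − p_e)/(1 − p_e)`. The standard error is the
  Fleiss–Cohen–Everitt large-sample variance of κ̂ (not the H₀ variance).
  Degenerate tables with `p_e = 1` raise an error.
- **Gwet's AC1**: `π` = mean of the raters' "clear" proportions,
  `p_e = 2π(1−π)`, same chance-correction form. The variance is Gwet's
  unconditional estimator, computed from the subject-level linearisation
  `γ*_s = γ_s − 2(1−γ̂)(p_{e|s} − p_e)/(1 − p_e)` with deviations taken
  around γ̂; cells contribute their identical subjects. A rater with an
  all-or-nothing marginal gives a *flagged* degenerate estimate rather than
  NaN, because rarely-requested examinations are a routine occurrence in
  per-exam reports.
- Confidence intervals are Wald on the coefficient scale at 95 %, clipped to
  [−1, 1]. Interpretation bands: ≥ 0.8 very good, ≥ 0.6 good, ≥ 0.4 moderate,
  ≥ 0.2 fair, else poor — each interval includes its upper breakpoint, so a
  coefficient exactly on a boundary takes the higher band (the verbal scale
  is ambiguous there; the convention is fixed and documented).
- The **z-comparison** of two coefficients uses
  `z = (κ₁ − κ₂)/√(se₁² + se₂²)` and treats the estimates as independent.
  When both approaches are rated on the *same* patients this ignores the
  pairing; with no published dependence correction this is a known,
  documented approximation — its p-values are indicative, not exact.
- The two-proportion test is the pooled z-test (statsmodels), continuity
  correction off by default and available via a flag.

## Synthetic data

The cohort generator's defaults encode the validation study's cohort: n=204,
age median 73 (IQR 64–79), 48.5 % female, BMI 25 (22–29), ASA 3 in 98 %,
surgical risk 10.3 / 64.2 / 25.5 % (low/intermediate/high), Charlson strata
22.5 / 54.4 / 10.8 / 1.5 / 10.8 % (0, 1–2, 3–4, ≥5, unknown), mortality-score
median 29 (26–32). Median/IQR summaries are modelled **log-normally by the
method of quantiles** (`μ = log median`, `σ = (log q₃ − log q₁)/(2·0.6745)`);
the exact family is a documented choice since only three quantiles are
published. Ages are integer-rounded and clipped to [18, 100].

Observation answers are filled with just enough structure for the pipeline to
exercise its range: cardiac risk-factor probability rises with the Charlson
stratum, poor functional capacity is likelier with ≥ 2 risk factors, the
high-risk-surgery flag tracks the surgical risk class, and the "unknown"
Charlson stratum is generated as explicit missingness. The generator does
**not** emulate true clinical joint distributions, outcome data, or
informative missingness — a green pipeline test establishes that generated
records are valid, evaluable, and marginally calibrated, nothing more.

Paired decisions with target κ\* invert the kappa definition: with
`p_e = pq + (1−p)(1−q)` and `δ = κ*(1−p_e)/2`, the cells are
`(pq+δ, p(1−q)−δ, (1−p)q−δ, (1−p)(1−q)+δ)`. Specs implying a negative cell
are rejected, never clipped — notably κ\* = 0.8 is infeasible at the study's
own skewed marginals (clearance 37/204 vs 97/204), which is why the recovery
tests use equal marginals for the upper grid point. Draws are i.i.d.
multinomial, so E[κ̂] = κ\* up to the estimator's O(1/n) bias. Exam-request
simulation solves the joint request probabilities from two marginal rates and
a target percent agreement, with the same feasibility guard.

A single root seed spawns independent sub-streams (cohort, ratings,
requests), so each generator is reproducible in isolation; identical
(profile, seed) gives byte-identical output.

## Reporting conventions

Percentages are rounded half-up (decimal arithmetic, not banker's rounding)
to one decimal — except the GRADE adherence percentage, which is reported to
the integer; coefficients are rendered to two decimals in markdown while the
JSON keeps full precision. Report counts always sum to N, and every printed
percentage equals its count/N under the stated rounding. Reports are
idempotent: same input, byte-identical JSON.

One reproduction caveat worth recording: in the validation study's published
primary-outcome table, the kappa computed from the digital column's own cell
counts (33, 4, 64, 103) is 0.31 and from the standard column's (91, 60, 6,
47) is 0.37 — the reverse of the labels printed next to them, while both
values and both printed intervals are reproduced exactly from the cells. All
package outputs are therefore bound to explicit cell counts, not to approach
labels. (The printed intervals, labelled interquartile ranges, coincide with
95 % Wald CIs; they are treated as such.)

## Known limitations

- The rule pack is a demonstrator; coverage of real guideline corpora is out
  of scope, as are authoring tools and inter-guideline conflict resolution
  beyond the source tag.
- The kappa z-comparison ignores the pairing of approaches on the same
  patients (above).
- The mortality points table is synthetic (above); Charlson/AKI/STOP-BANG
  tables are transcriptions of the standard published structures and are
  versioned data, replaceable without code changes.
- Multi-category (> 2) agreement coefficients are not implemented; all
  decisions are binary clear/reject.
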