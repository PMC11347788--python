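# preopeval

A toolkit for **digital guideline support in preoperative evaluation** and for
the **agreement studies** used to validate it. It is aimed at researchers in
perioperative medicine and clinical-decision-support engineering who want to
(a) encode guideline recommendations as executable, auditable data rather than
prose, and (b) quantify how well two evaluation approaches (e.g. a
guideline-support tool and routine clinical practice) agree with an expert's
clearance-for-surgery decisions.

## What it implements

**Rule engine.** Guideline recommendations are stored as data files:
dichotomous decision trees or AND/OR boolean expressions over hierarchically
organised patient observations (dotted ids such as `2.2.1`) and named risk
scores. Evaluation uses Kleene three-valued logic — a missing answer makes a
rule *unknown*, and the engine reports the blocking observations as mandatory
fields instead of guessing. Each rule condition carries a GRADE class
(strength 1/2 × evidence quality A/B/C); when several conditions fire, only
the highest-GRADE one is displayed (1A > 1B > 1C > 2A > 2B > 2C > none). A
patient is **cleared for surgery** iff no fired rule recommends an
examination.

**Risk scores.** Revised Cardiac Risk Index (5-item clinical-factor count and
6-item total), Charlson Comorbidity Index (weights 1/2/3/6), STOP-BANG,
a preoperative mortality points score, and the general-surgery acute kidney
injury risk index. All point tables ship as versioned YAML data; the code only
does weighted sums, counts and lookups, and missing inputs yield *unknown*,
never an imputed zero.

**Agreement statistics.** For a 2×2 cross-classification of an approach's
clear/reject decisions against a reference with cells *a* (both clear), *b*,
*c*, *d* (both reject), *N = a+b+c+d*:

- observed agreement `p_o = (a+d)/N`;
- **Cohen's κ** `= (p_o − p_e)/(1 − p_e)` with `p_e` from the product of the
  raters' marginals, SE by the Fleiss–Cohen–Everitt large-sample variance;
- **Gwet's AC1** with chance term `2π(1−π)`, `π` the mean of the two raters'
  "clear" proportions, and Gwet's unconditional variance — robust when
  marginals are skewed;
- a z-test comparing two coefficients, the four-way decision classification
  (correctly cleared / correctly rejected / not followed / incorrectly
  rejected), two-proportion tests, and Landis–Koch-style interpretation bands
  (≥0.8 very good, ≥0.6 good, ≥0.4 moderate, ≥0.2 fair, else poor).

**Synthetic data.** Cohort generator matching a configurable marginal profile
(default: 204 elderly ASA 3–4 elective surgical patients, median age 73,
48.5 % female, surgical risk 10.3/64.2/25.5 % low/intermediate/high), and a
paired-decision generator that inverts the kappa definition into four cell
probabilities for controlled marginals and target κ, with a feasibility guard.

## Worked example

```python
from preopeval import TwoByTwo, cohen_kappa, gwet_ac1
from preopeval.pipeline import table2_report, triplets_from_tables

digital = TwoByTwo(a=33, b=4, c=64, d=103)    # digital support vs expert
standard = TwoByTwo(a=91, b=60, c=6, d=47)    # standard practice vs expert

k = cohen_kappa(digital)
print(round(k.coef, 2), k.band, [round(x, 2) for x in k.ci])
print(round(gwet_ac1(digital).coef, 2))

report = table2_report(*triplets_from_tables(digital, standard))
print(report["approaches"]["digital"]["clearance_rate"],
      report["approaches"]["standard"]["clearance_rate"],
      report["reference_clearance_rate"])
```

prints

```
0.31 fair [0.21, 0.42]
0.4
18.1 74.0 47.5
```

i.e. chance-corrected agreement between the digital approach and the expert
is fair (κ = 0.31, 95 % CI 0.21–0.42; AC1 = 0.40), and the three approaches
cleared 18.1 %, 74.0 % and 47.5 % of the 204 patients respectively.

The command line mirrors the library: `preopeval evaluate` (rule engine over
a cohort), `preopeval score`, `preopeval agree`, `preopeval simulate
cohort|ratings|requests`, and `preopeval report table2|exams`. Try

```bash
preopeval simulate cohort --n 20 --seed 3 --out cohort.csv
preopeval evaluate --rules src/preopeval/data/rulepack.yaml --cohort cohort.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes the study-level summary quantities from
scratch: it expands the published primary-outcome cell counts into
per-patient decision vectors, runs the agreement/reporting pipeline on them,
computes the GRADE-stratum arithmetic, and writes the results as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The seed shuffles patient order; all reported statistics are
permutation-invariant.

## Layout

- `src/preopeval/observations.py` — typed observation hierarchy with
  conditional activation and cascade invalidation
- `src/preopeval/rules.py` — rule engine, strict rule-file loader
  (`data/rule_schema.json` documents the format)
- `src/preopeval/scores.py` — data-driven score calculators
  (`data/*.yaml` tables; the mortality points table is a checksummed
  *synthetic* stand-in, see `docs/methods.md`)
- `src/preopeval/agreement.py` — κ, AC1, tests, bands
- `src/preopeval/simulate.py` — cohort / paired-ratings / exam-request
  generators
- `src/preopeval/pipeline.py` — primary-outcome, per-exam and GRADE reports
- `docs/methods.md` — models, assumptions, numerical choices, limitations
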