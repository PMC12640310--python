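# criteriagraph

Fine-grained clinical-trial matching — deciding whether a specific patient
satisfies criteria like *"at least 14 days must have elapsed between the last
anticancer treatment and randomization"* — requires extracting many discrete
data points from unstructured clinical notes and combining them through
logical and temporal reasoning. `criteriagraph` is a toolkit for the people
building and studying such pipelines: clinical research informaticists who
structure eligibility criteria for automated prescreening, and methodologists
who want to quantify how computationally demanding a protocol's criteria are.

The package structures each criterion as a hierarchy of variables:

- an **independent variable** is a discrete unit of data extracted directly
  from clinical text (a timestamp, a lab value, a boolean finding), with a
  declared data type, a **scope** (many values per note, one per note, or one
  per patient) and an aggregation strategy (most recent by default);
- a **dependent variable** computes a value from other variables through a
  small logic grammar (boolean composition, comparisons, temporal gaps,
  arithmetic, counts) and never reads text itself.

Variables form a directed acyclic graph; criteria point at boolean-typed
roots, conjunctive for inclusion criteria and disjunctive for exclusion
criteria by default.

On top of that representation the package provides:

- **Complexity scoring.** A criterion whose closure contains *I* unique
  independent variables and *D* dependent variables scores
  *C = I · 2^D*; total trial complexity is the sum over criteria. Each
  retrieval costs one unit, and every layered combination step doubles the
  burden.
- **Readability profiling.** Word, sentence and syllable counts and the
  Flesch-Kincaid grade level *0.39·(W/S) + 11.8·(Syl/W) − 15.59* of each
  criterion's verbatim text, with a fixed, documented tokenizer and syllable
  heuristic.
- **Correlation.** Spearman rank correlation (average-rank ties; two-sided
  t-approximation or exact-permutation p-values) between complexity and the
  text metrics.
- **Eligibility evaluation.** Aggregates per-note observations under each
  variable's scope, evaluates the DAG bottom-up, and combines criterion
  statuses under Kleene three-valued logic, so missing data and
  indeterminate variables surface as *unknown* ("needs human review") rather
  than silently excluding a patient.
- **Synthetic data.** Seeded generators for protocols and patient records
  whose composition mirrors a heavily decomposed real oncology protocol
  (boolean-dominant types, one-per-patient-dominant scopes, ~18% dependent
  variables), plus an independent brute-force evaluator used as a test
  oracle.

## Worked example

The package bundles a five-criterion example protocol
(`criteriagraph.worked_examples()`) ranging from a single extracted boolean
to a three-sub-criterion hierarchy that reuses four of its eight independent
variables:

```bash
python -c "from criteriagraph import worked_examples; \
           from criteriagraph.io_cli import write_protocol; \
           write_protocol(worked_examples(), 'examples.json')"
criteriagraph score examples.json --out-csv scores.csv
```

prints the trial-level summary

```
{"median": 8.0, "q1": 3.0, "q3": 56.0, "quantile_method": "linear", "total": 132}
```

and writes per-criterion scores:

```
criterion_id,I,D,C
ex1,1,0,1
ex2,3,0,3
ex3,2,2,8
ex4,7,3,56
ex5,8,3,64
```

`ex1` ("Not previously HER2 + on pathology testing.") needs one extraction
and no combination: C = 1. `ex4`, the cardiovascular-history exclusion,
needs seven extractions combined through three sub-criterion conditions:
C = 7·2³ = 56. `ex5` touches eight *unique* independents — four of them on
multiple paths, counted once each — through three dependents: C = 8·2³ = 64.
The trial total is the sum, 132, with median criterion complexity 8.

Readability for the same file:

```
$ criteriagraph readability examples.json
criterion_id,word_count,sentence_count,syllable_count,fk_grade
ex1,6,1,13,12.3167
ex2,20,1,31,10.5
...
```

A complete simulate → evaluate loop:

```bash
criteriagraph simulate --seed 11 --n-patients 4 \
    --out-protocol protocol.json --out-patients patients.json
criteriagraph evaluate --protocol protocol.json \
    --patients patients.json --out verdicts.jsonl
# {"false": 4, "patients": 4, "true": 0, "unknown": 0}
```

Each JSONL row carries the patient's overall three-valued verdict and
per-criterion statuses (plus per-variable traces with `--trace`).

Other subcommands: `validate` (structural findings with error/warning
severities), `report` (summary, per-criterion, correlation and box-plot
CSVs for one or more protocols), `correlate` (Spearman rho between two CSV
columns).

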