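# Methods

## The representation

A trial protocol is a registry of variables plus an ordered list of
criteria. Independent variables model single extraction tasks over clinical
notes: each carries a data type (`integer`, `float`, `boolean`, `timestamp`,
`text`, or `indeterminate` for data that fits no standard type, such as
eligibility judged by clinician intuition), a scope, and an aggregation
strategy. Dependent variables model combination steps: an ordered input list
and a logic expression, never reading text. Edges run input → dependent, and
the graph must be acyclic; evaluation order is a lexicographic topological
sort (deterministic tie-break by variable id).

Criteria reference boolean-typed root variables. A criterion with several
roots and no dependent variable combines them with a criterion-level
combinator (`all` for inclusion, `any` for exclusion, overridable per
criterion). The combinator is *not* a dependent variable: a flat
three-extraction criterion scores C = 3, not 6. This keeps dependent counts
tied to explicitly modelled computation steps, at the cost that a flat root
list cannot express mixed and/or semantics — such criteria need an explicit
dependent variable.

Sub-criteria (the a/b/c structure common in oncology protocols) are modelled
as dependent variables feeding one criterion, not as separate criteria: a
lettered criterion is still scored, profiled and reported as one unit.

### The logic grammar

The expression language is deliberately small: `and/or/not`, comparisons
(`eq ne lt le gt ge`), arithmetic (`add`, `sub`), `count` over list-valued
inputs, `temporal_gap` between two timestamps, typed literals and input
references. This is the smallest grammar that expresses the decompositions
we model (washout-period checks, "within 6 months of enrollment" windows,
threshold comparisons like LVEF < 40%, boolean composition of findings).
Expressions are statically type-checked: the result type must equal the
owning variable's declared type, comparisons require operands of one family,
and `indeterminate` inputs are admissible anywhere (they evaluate to
unknown, never to a type error).

`temporal_gap(a, b)` is signed, `a − b`, in days, or months with a fixed
30.4375-day month. Criteria such as "within 6 months" need one documented
convention; calendar-month arithmetic was rejected because it makes gap
length depend on which month the anchor falls in.

## Complexity scoring

C = I · 2^D, where I is the number of *unique* independent variables in the
criterion's dependency closure and D the number of dependent variables.
Uniqueness matters: an independent variable reachable through several paths
is one extraction task and is counted once (set semantics in the closure).
Scores use exact integer arithmetic at any depth — Python integers are
arbitrary-precision, so no overflow cap is needed. Criteria whose closure
contains no independent variable are refused (`NO_INDEPENDENTS`) rather than
scored 0: a criterion with no extractable data is meaningless under the
framework.

Total trial complexity sums per-criterion scores without cross-criterion
deduplication: two criteria sharing an extraction each pay for it, since a
screening pipeline evaluates each criterion's logic separately.

Distribution summaries (median, quartiles) default to linear interpolation
between order statistics; the method is switchable (`--quantile-method`) and
recorded in the report, since published IQRs rarely disclose their quantile
convention.

## Readability

Flesch-Kincaid grade = 0.39·(words/sentences) + 11.8·(syllables/words)
− 15.59, unclamped (it may be negative for very simple text, or very large
for single-word fragments).

Published readability calculators disagree in unpublished tokenizer and
syllable details, so this module fixes its own deterministic rules and
documents them:

- **Words**: whitespace tokens containing at least one alphanumeric
  character; pure punctuation tokens (a stray `+`) are dropped; hyphenated
  words count once.
- **Sentences**: split on `. ! ? ;` followed by whitespace or end, and on
  newlines, so bullet-point fragments without terminal punctuation count as
  one sentence each; a non-empty text has at least one sentence.
- **Syllables**: one per vowel group (a e i o u y); a terminal silent 'e' is
  subtracted except in consonant+'le' endings ("stable" keeps 2); numerals
  contribute the syllables of their digit-by-digit reading ("14" → one-four
  → 2); hyphenated parts sum; floor at 1. The heuristic misses internal
  silent e's ("baseline" → 3), an accepted bias of vowel-group counting.

Grades computed here are therefore reproducible but may differ by fractions
of a grade from web calculators; rank-based analyses (the Spearman
correlations) are insensitive to such monotone-ish discrepancies.

## Correlation

Spearman's rho is the Pearson correlation of average-rank vectors (ties get
the mean of their rank range). Two-sided p-values use the t approximation
with n−2 degrees of freedom by default, matching common statistical
software; an exact permutation mode (all n! permutations, n ≤ 10) is
provided for small trials. Constant inputs leave rho undefined and raise an
error rather than returning NaN. n ≥ 3 is required; the report marks smaller
trials' correlation rows not-computable.

## Eligibility evaluation

Per variable: observations are collapsed under the variable's scope —
`many_per_note` keeps all values (in note-stream order), `one_per_note`
applies the strategy within each note, `one_per_patient` across all notes.
Strategies: `first_value`/`last_value` use note-stream order;
`earliest_occurrence`/`latest_occurrence` return the observation *dates*;
`most_recent` (the default) returns the value carried by the newest
observation; `most_frequent` returns the modal value, ties broken toward
the value whose earliest observation is older (deterministic). Time-based
strategies require timestamps on every observation (`NO_TIMESTAMP`
otherwise); an observation without its own timestamp inherits its note's.

Missing data uses Kleene's strong three-valued logic: a variable with no
observations is *unknown*; `and(false, unknown) = false`,
`or(true, unknown) = true`, everything else involving unknown stays unknown;
comparisons, arithmetic and temporal gaps with an unknown operand are
unknown. Indeterminate variables always evaluate unknown and carry their
payload in the trace for human review. Binary evaluation was rejected
because incomplete or inconsistently coded EHR data would otherwise silently
exclude patients; an unknown verdict is an explicit needs-human-review
outcome, and the policy for acting on it is left to the caller.

Overall verdict: conjunction of all inclusion statuses AND the negated
disjunction of all exclusion statuses, three-valued throughout. An exclusion
criterion with status true means "excluded".

## Synthetic data

The generator emulates the variable-level composition of a large,
fine-grained oncology protocol: 39 criteria; independents per criterion
drawn from a right-skewed distribution with mean ≈ 3.3 and median 2;
dependent share 18% (29/160); data-type weights boolean 111, timestamp 24,
text 14, indeterminate 7, integer 2, float 2 (out of 160); scope weights
one-per-patient 153, many-per-note 4, one-per-note 3. Structural constraints
force some assignments (dependents and direct boolean roots are boolean and
one-per-patient), so the remaining free slots are allocated by largest
remainder against the weights, keeping realized shares within a couple of
percentage points of the targets. Dependents draw inputs only from
earlier-generated variables of the same criterion, guaranteeing acyclicity
by construction; every generated protocol validates cleanly, and generation
is byte-deterministic per seed (one `random.Random` stream, no global
state).

Patient records: a configurable number of notes per patient (default 5)
with strictly increasing timestamps; each independent variable is observed
with probability 1 − missingness_rate (default 0.1; equivalence sweeps use
0.3 to exercise unknowns); values are drawn type-appropriately.

What the generator does **not** emulate: real note text (observations are
structured values — the extraction layer is out of scope), correlations
between clinically related variables, criterion text whose linguistic
difficulty tracks its decomposition (synthetic texts are templated), and
longitudinal disease dynamics. Passing tests on synthetic data therefore
demonstrate the correctness of structuring, scoring and evaluation — not
extraction accuracy on real notes.

The brute-force oracle (`brute_force_eligibility`) re-states the evaluation
semantics independently — plain recursion, no memoization, its own
aggregation and three-valued rules, `None` as the missing marker — and is
capped at 20 variables. Agreement between engine and oracle on hundreds of
seeded (protocol, record) pairs is the core correctness evidence for the
evaluator.

## Problem sizes and numerical choices

The default test and acceptance runs use: 1,000 (I, D) draws for the scoring
law (I ≤ 50, D ≤ 10); 200 seeded protocols for the unique-count property;
500 (protocol, record) pairs at ≤ 12 variables and 30% missingness for
engine/oracle equivalence; 100 protocols for serialization identity; 20
seeds for generator composition checks; exact-permutation validation up to
n = 7 (5,040 permutations). These sizes give binomial/permutation resolution
comfortably inside the asserted bands while the whole suite runs in
seconds.

Box-plot CSVs use 1.5×IQR fences beyond the quartiles (the standard Tukey
rule); whiskers are the extreme values inside the fences and outliers are
listed explicitly.

## Known limitations

- The flat-roots combinator cannot express mixed conjunctive/disjunctive
  criteria without an explicit dependent variable.
- The syllable heuristic is approximate (see above); absolute grades are
  comparable within this package, not across tools.
- Readability captures linguistic difficulty only, not the clinical
  cognitive burden of a criterion.
- Complexity weights every extraction and combination equally; no
  distinction by data type or retrieval difficulty.
- Timestamps are naive datetimes; time zones are out of scope.
- A full real-trial decomposition (dozens of criteria with verbatim
  protocol text) is not bundled; the loader accepts one as ordinary
  protocol JSON when available.
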