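"""Seeded generators for synthetic protocols and patient records.

The defaults emulate the variable-level make-up of a real, heavily
decomposed phase-3 oncology protocol: 39 criteria, ~3.3 independent
variables per criterion with a right-skewed spread, 18% dependent variables,
boolean-dominant data types (111/160) and one-per-patient-dominant scopes
(153/160).  Generated protocols always pass structural validation and their
dependents' logic expressions type-check by construction (dependents only
ever reference earlier-generated variables, so the graph is acyclic).

Also hosts ``brute_force_eligibility``, a deliberately naive recursive
evaluator (no memoization, no shared code with the evaluation engine) used
as the independent oracle in equivalence tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

from .model import (
    AggregationStrategy,
    Criterion,
    DataType,
    LogicNode,
    Scope,
    TrialProtocol,
    VariableDef,
    and_,
    cmp,
    count,
    lit,
    not_,
    or_,
    temporal_gap,
    var,
)
from .evaluate import (
    UNKNOWN,
    EligibilityVerdict,
    CriterionOutcome,
    Note,
    Observation,
    PatientRecord,
    TriValue,
)

__all__ = [
    "SynthConfig",
    "generate_protocol",
    "generate_patient_records",
    "brute_force_eligibility",
]

_BASE_DATE = datetime(2024, 1, 1)
_WORDS = ("positive", "negative", "stable", "progressive", "resolved", "active")

# Trial-A-like defaults (counts over 160 variables)
_DEFAULT_TYPE_WEIGHTS = {
    "boolean": 111, "timestamp": 24, "text": 14,
    "indeterminate": 7, "integer": 2, "float": 2,
}
_DEFAULT_SCOPE_WEIGHTS = {"one_per_patient": 153, "many_per_note": 4, "one_per_note": 3}
# right-skewed independents-per-criterion distribution, mean ~3.2, median 2
_DEFAULT_INDEP_COUNTS = {1: 12, 2: 9, 3: 6, 4: 4, 5: 3, 6: 2, 8: 1.5, 12: 1, 20: 0.5}


@dataclass
class SynthConfig:
    """Knobs of the synthetic study population.

    ``dependent_fraction`` is the target share of dependent variables among
    all variables; ``missingness_rate`` the per-patient probability that an
    independent variable is never observed.
    """

    n_criteria: int = 39
    independent_count_distribution: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_INDEP_COUNTS)
    )
    dependent_fraction: float = 29 / 160
    data_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_WEIGHTS)
    )
    scope_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SCOPE_WEIGHTS)
    )
    missingness_rate: float = 0.1
    notes_per_patient: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_criteria < 0:
            raise ValueError("n_criteria must be >= 0")
        if not (0.0 <= self.dependent_fraction <= 0.5):
            raise ValueError("dependent_fraction must lie in [0, 0.5]")
        if not (0.0 <= self.missingness_rate <= 1.0):
            raise ValueError("missingness_rate must lie in [0, 1]")
        for name, weights in (
            ("independent_count_distribution", self.independent_count_distribution),
            ("data_type_weights", self.data_type_weights),
            ("scope_weights", self.scope_weights),
        ):
            if not weights or any(w < 0 for w in weights.values()) or not any(
                w > 0 for w in weights.values()
            ):
                raise ValueError(f"{name} must have non-negative, normalizable weights")
        if self.dependent_fraction > 0 and all(
            c == 0 or w == 0 for c, w in self.independent_count_distribution.items()
        ):
            raise ValueError("dependents require criteria with >= 1 independent")


def _allocate(total: int, weights: dict[str, float], forced: dict[str, int]) -> list[str]:
    """Largest-remainder allocation of ``total`` labels matching ``weights``
    as closely as possible given ``forced`` counts already committed."""
    wsum = sum(weights.values())
    targets = {k: total * w / wsum for k, w in weights.items()}
    free = total - sum(forced.values())
    residual = {k: max(0.0, targets[k] - forced.get(k, 0)) for k in weights}
    rsum = sum(residual.values()) or 1.0
    quota = {k: free * residual[k] / rsum for k in weights}
    alloc = {k: int(quota[k]) for k in weights}
    leftover = free - sum(alloc.values())
    for k in sorted(weights, key=lambda k: quota[k] - alloc[k], reverse=True):
        if leftover <= 0:
            break
        alloc[k] += 1
        leftover -= 1
    out: list[str] = []
    for k, n in alloc.items():
        out.extend([k] * n)
    return out


def _bool_atom(v: VariableDef, rng: random.Random) -> LogicNode:
    """A boolean expression over one input variable, valid for its type/scope."""
    if v.data_type is DataType.INDETERMINATE:
        return var(v.id)  # evaluates to unknown; admissible in boolean position
    if v.is_independent and v.scope is not Scope.ONE_PER_PATIENT:
        # list-valued inputs are only usable through count()
        return cmp("ge", count(var(v.id)), lit(rng.randint(1, 3), "integer"))
    if v.data_type is DataType.BOOLEAN:
        return not_(var(v.id)) if rng.random() < 0.25 else var(v.id)
    if v.data_type is DataType.INTEGER:
        return cmp(rng.choice(("ge", "le", "gt", "lt")), var(v.id),
                   lit(rng.randint(0, 9), "integer"))
    if v.data_type is DataType.FLOAT:
        return cmp(rng.choice(("ge", "le")), var(v.id),
                   lit(round(rng.uniform(0, 100), 1), "float"))
    if v.data_type is DataType.TIMESTAMP:
        anchor = _BASE_DATE + timedelta(days=rng.randint(0, 365))
        return cmp(rng.choice(("ge", "le")),
                   temporal_gap(lit(anchor, "timestamp"), var(v.id)),
                   lit(rng.randint(7, 180), "integer"))
    # text
    return cmp("eq", var(v.id), lit(rng.choice(_WORDS), "text"))


def generate_protocol(config: SynthConfig) -> TrialProtocol:
    """A random protocol with the configured statistical structure.

    Deterministic for a fixed config (including seed): two calls serialize
    byte-identically.  Always validates with zero errors.
    """
    config.validate()
    rng = random.Random(config.seed)

    counts = sorted(config.independent_count_distribution.items())
    ks = [c for c, _ in counts]
    ws = [w for _, w in counts]
    k_per = [rng.choices(ks, weights=ws)[0] for _ in range(config.n_criteria)]

    f = config.dependent_fraction
    d_per: list[int] = []
    for k in k_per:
        if f <= 0 or k == 0:
            d_per.append(0)
            continue
        mean = k * f / (1 - f)
        d = int(mean) + (1 if rng.random() < mean - int(mean) else 0)
        d_per.append(d)

    n_total = sum(k_per) + sum(d_per)
    # data types: dependents and the roots of dependent-free criteria must be
    # boolean; allocate the remaining slots so the overall mix tracks the
    # configured weights
    forced_bool = sum(d_per) + sum(k for k, d in zip(k_per, d_per) if d == 0)
    # _allocate returns labels for the free slots only (forced already netted)
    pool_types = _allocate(n_total, config.data_type_weights,
                           {"boolean": forced_bool})
    rng.shuffle(pool_types)

    # scopes: dependents compute one value per patient, and direct boolean
    # roots must be scalar, so both are forced one_per_patient
    forced_opp = sum(d_per) + sum(k for k, d in zip(k_per, d_per) if d == 0)
    pool_scopes = _allocate(n_total, config.scope_weights,
                            {"one_per_patient": forced_opp})
    rng.shuffle(pool_scopes)

    variables: dict[str, VariableDef] = {}
    criteria: list[Criterion] = []
    for idx, (k, d) in enumerate(zip(k_per, d_per), start=1):
        cid = f"c{idx:03d}"
        indeps: list[VariableDef] = []
        for j in range(1, k + 1):
            if d == 0:
                dtype, scope = "boolean", "one_per_patient"
            else:
                dtype = pool_types.pop() if pool_types else "boolean"
                scope = pool_scopes.pop() if pool_scopes else "one_per_patient"
            v = VariableDef(
                id=f"{cid}_i{j}",
                name=f"extracted finding {j} for criterion {idx}",
                dependency="independent",
                data_type=DataType(dtype),
                scope=Scope(scope),
                aggregation=rng.choice(
                    (AggregationStrategy.MOST_RECENT,
                     AggregationStrategy.MOST_RECENT,
                     AggregationStrategy.MOST_FREQUENT,
                     AggregationStrategy.FIRST_VALUE,
                     AggregationStrategy.LAST_VALUE)
                ),
                instructions=f"extract finding {j} supporting criterion {idx}",
            )
            indeps.append(v)
            variables[v.id] = v

        deps: list[VariableDef] = []
        if d > 0:
            # deal every independent to some dependent, then draw extras
            assigned: list[list[VariableDef]] = [[] for _ in range(d)]
            for v in indeps:
                assigned[rng.randrange(d)].append(v)
            for j in range(1, d + 1):
                inputs = list(assigned[j - 1])
                # dependents may also consume earlier dependents
                for earlier in deps:
                    if rng.random() < 0.3:
                        inputs.append(earlier)
                if j == d:  # root: absorb any dependent not yet consumed
                    consumed = {i for dep in deps for i in dep.inputs}
                    for earlier in deps:
                        if earlier.id not in consumed and all(
                            earlier.id != x.id for x in inputs
                        ):
                            inputs.append(earlier)
                if not inputs:
                    inputs.append(rng.choice(indeps + deps[: j - 1]))
                # dedupe, keep order
                seen: set[str] = set()
                inputs = [x for x in inputs
                          if not (x.id in seen or seen.add(x.id))]
                atoms = [_bool_atom(x, rng) for x in inputs]
                if len(atoms) == 1:
                    # a bare indeterminate reference types as indeterminate;
                    # a 1-ary conjunction coerces it into boolean position
                    expr = atoms[0] if atoms[0].op != "var" else and_(atoms[0])
                else:
                    expr = and_(*atoms) if rng.random() < 0.5 else or_(*atoms)
                dep = VariableDef(
                    id=f"{cid}_d{j}",
                    name=f"derived condition {j} for criterion {idx}",
                    dependency="dependent",
                    data_type=DataType.BOOLEAN,
                    scope=Scope.ONE_PER_PATIENT,
                    inputs=tuple(x.id for x in inputs),
                    logic=expr,
                )
                deps.append(dep)
                variables[dep.id] = dep
            roots = (deps[-1].id,)
        else:
            roots = tuple(v.id for v in indeps)

        kind = rng.choice(("inclusion", "inclusion", "exclusion"))
        criteria.append(
            Criterion(
                id=cid,
                text=f"Synthetic criterion {idx} combining {k} extracted "
                     f"findings and {d} derived conditions.",
                kind=kind,
                roots=roots,
            )
        )

    return TrialProtocol(
        id=f"synthetic-{config.seed}",
        name=f"synthetic protocol (seed {config.seed})",
        criteria=criteria,
        variables=variables,
    )


def _random_value(dtype: DataType, rng: random.Random):
    if dtype is DataType.BOOLEAN:
        return rng.random() < 0.5
    if dtype is DataType.INTEGER:
        return rng.randint(0, 10)
    if dtype is DataType.FLOAT:
        return round(rng.uniform(0, 100), 2)
    if dtype is DataType.TIMESTAMP:
        return _BASE_DATE + timedelta(days=rng.randint(0, 365))
    if dtype is DataType.TEXT:
        return rng.choice(_WORDS)
    return "requires clinician judgement"  # indeterminate payload


def generate_patient_records(
    protocol: TrialProtocol, n_patients: int, config: SynthConfig
) -> list[PatientRecord]:
    """Synthetic patient note streams consistent with the protocol.

    Each independent variable is observed with probability
    1 - missingness_rate per patient; note timestamps are strictly increasing
    within a patient.  Deterministic for fixed (protocol, config).
    """
    config.validate()
    rng = random.Random(f"{config.seed}:records")
    indep = [v for v in protocol.variables.values() if v.is_independent]
    records: list[PatientRecord] = []
    for p in range(1, n_patients + 1):
        notes = [
            Note(
                note_id=f"p{p:04d}_n{j}",
                timestamp=_BASE_DATE + timedelta(days=30 * j + rng.randint(0, 29)),
            )
            for j in range(config.notes_per_patient)
        ]
        for v in indep:
            if rng.random() < config.missingness_rate:
                continue
            if v.scope is Scope.ONE_PER_PATIENT:
                homes = [rng.randrange(len(notes))]
            else:
                n_home = rng.randint(1, len(notes))
                homes = sorted(rng.sample(range(len(notes)), n_home))
            for h in homes:
                reps = rng.randint(1, 3) if v.scope is Scope.MANY_PER_NOTE else 1
                for _ in range(reps):
                    notes[h].observations.append(
                        Observation(
                            variable_id=v.id,
                            value=_random_value(v.data_type, rng),
                            needs_human=v.data_type is DataType.INDETERMINATE,
                        )
                    )
        records.append(PatientRecord(patient_id=f"p{p:04d}", notes=notes))
    return records


# --------------------------------------------------------------------------
# Independent brute-force oracle
# --------------------------------------------------------------------------
# This is intentionally a from-scratch re-statement of the evaluation
# semantics: plain recursion, no memoization, None as the missing-value
# marker, and its own copies of the aggregation and Kleene rules.  It shares
# no code with evaluate.py so that agreement between the two is evidence,
# not tautology.


def _bf_aggregate(pairs, scope: Scope, strategy: AggregationStrategy):
    """pairs: list of (timestamp, order_index, value), note-stream order."""
    if not pairs:
        return None
    if scope is Scope.MANY_PER_NOTE:
        return [v for _, _, v in pairs]

    def pick(group):
        s = strategy
        if s in (AggregationStrategy.EARLIEST_OCCURRENCE,
                 AggregationStrategy.LATEST_OCCURRENCE,
                 AggregationStrategy.MOST_RECENT):
            if any(t is None for t, _, _ in group):
                raise ValueError("NO_TIMESTAMP")
        if s is AggregationStrategy.FIRST_VALUE:
            return group[0][2]
        if s is AggregationStrategy.LAST_VALUE:
            return group[-1][2]
        if s is AggregationStrategy.EARLIEST_OCCURRENCE:
            return min(t for t, _, _ in group)
        if s is AggregationStrategy.LATEST_OCCURRENCE:
            return max(t for t, _, _ in group)
        if s is AggregationStrategy.MOST_RECENT:
            best = group[0]
            for g in group[1:]:
                if (g[0], g[1]) >= (best[0], best[1]):
                    best = g
            return best[2]
        if s is AggregationStrategy.MOST_FREQUENT:
            tally: dict = {}
            first: dict = {}
            for t, i, v in group:
                tally[v] = tally.get(v, 0) + 1
                key = (t if t is not None else datetime.max, i)
                if v not in first or key < first[v]:
                    first[v] = key
            top = max(tally.values())
            cands = [v for v, c in tally.items() if c == top]
            cands.sort(key=lambda v: first[v])
            return cands[0]
        raise ValueError(f"unknown strategy {s}")

    if scope is Scope.ONE_PER_PATIENT:
        return pick(pairs)
    # one_per_note: group by contiguous note id (pairs carry note id in slot 1)
    raise AssertionError("one_per_note handled by caller")


def _bf_expr(node: LogicNode, env: dict):
    op = node.op
    if op == "lit":
        return node.value
    if op == "var":
        return env[node.var_id]
    if op == "not":
        a = _bf_expr(node.args[0], env)
        return None if a is None else (not a)
    if op == "and":
        vals = [_bf_expr(a, env) for a in node.args]
        if any(v is False for v in vals):
            return False
        if any(v is None for v in vals):
            return None
        return True
    if op == "or":
        vals = [_bf_expr(a, env) for a in node.args]
        if any(v is True for v in vals):
            return True
        if any(v is None for v in vals):
            return None
        return False
    if op == "count":
        a = _bf_expr(node.args[0], env)
        if a is None:
            return None
        return len(a) if isinstance(a, list) else 1
    vals = [_bf_expr(a, env) for a in node.args]
    if any(v is None for v in vals):
        return None
    if op == "temporal_gap":
        days = (vals[0] - vals[1]).total_seconds() / 86400.0
        return days / 30.4375 if node.unit == "months" else days
    if op == "add":
        return vals[0] + vals[1]
    if op == "sub":
        return vals[0] - vals[1]
    if op == "eq":
        return vals[0] == vals[1]
    if op == "ne":
        return vals[0] != vals[1]
    if op == "lt":
        return vals[0] < vals[1]
    if op == "le":
        return vals[0] <= vals[1]
    if op == "gt":
        return vals[0] > vals[1]
    if op == "ge":
        return vals[0] >= vals[1]
    raise ValueError(f"unknown op {op}")


def brute_force_eligibility(
    protocol: TrialProtocol, record: PatientRecord
) -> EligibilityVerdict:
    """Reference verdict by naive recursive recomputation (<= 20 variables)."""
    if len(protocol.variables) > 20:
        raise ValueError("brute-force oracle refuses protocols with > 20 variables")

    def value_of(vid: str):
        v = protocol.variables[vid]
        if v.dependency == "independent":
            if v.data_type is DataType.INDETERMINATE:
                return None
            pairs = []
            order = 0
            by_note: dict = {}
            note_order: list = []
            for note in record.notes:
                for obs in note.observations:
                    if obs.variable_id == vid:
                        t = obs.observed_at or note.timestamp
                        pairs.append((t, order, obs.value))
                        by_note.setdefault(note.note_id, []).append(
                            (t, order, obs.value)
                        )
                        if note.note_id not in note_order:
                            note_order.append(note.note_id)
                        order += 1
            if not pairs:
                return None
            if v.scope is Scope.ONE_PER_NOTE:
                return [
                    _bf_aggregate(by_note[nid], Scope.ONE_PER_PATIENT, v.aggregation)
                    for nid in note_order
                ]
            return _bf_aggregate(pairs, v.scope, v.aggregation)
        env = {i: value_of(i) for i in v.inputs}
        return _bf_expr(v.logic, env)

    def tri(b) -> TriValue:
        if b is None:
            return TriValue.UNKNOWN
        return TriValue.TRUE if b else TriValue.FALSE

    outcomes = []
    inc, exc = [], []
    for c in protocol.criteria:
        root_vals = [tri(value_of(r)) for r in c.roots]
        if c.combinator == "all":
            if any(v is TriValue.FALSE for v in root_vals):
                status = TriValue.FALSE
            elif any(v is TriValue.UNKNOWN for v in root_vals):
                status = TriValue.UNKNOWN
            else:
                status = TriValue.TRUE
        else:
            if any(v is TriValue.TRUE for v in root_vals):
                status = TriValue.TRUE
            elif any(v is TriValue.UNKNOWN for v in root_vals):
                status = TriValue.UNKNOWN
            else:
                status = TriValue.FALSE
        outcomes.append(CriterionOutcome(c.id, status, {}))
        (inc if c.kind == "inclusion" else exc).append(status)

    def all3(vals):
        if any(v is TriValue.FALSE for v in vals):
            return TriValue.FALSE
        if any(v is TriValue.UNKNOWN for v in vals):
            return TriValue.UNKNOWN
        return TriValue.TRUE

    def any3(vals):
        if any(v is TriValue.TRUE for v in vals):
            return TriValue.TRUE
        if any(v is TriValue.UNKNOWN for v in vals):
            return TriValue.UNKNOWN
        return TriValue.FALSE

    not_excluded = {
        TriValue.TRUE: TriValue.FALSE,
        TriValue.FALSE: TriValue.TRUE,
        TriValue.UNKNOWN: TriValue.UNKNOWN,
    }[any3(exc)] if exc else TriValue.TRUE
    overall = all3([all3(inc) if inc else TriValue.TRUE, not_excluded])
    return EligibilityVerdict(record.patient_id, overall, outcomes)
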