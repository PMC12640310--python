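"""Patient eligibility evaluation over structured criteria.

A patient record is a stream of timestamped notes carrying observations of
the protocol's independent variables.  Evaluation first collapses each
independent variable's observations under its scope and aggregation strategy,
then computes dependent variables bottom-up through the dependency graph, and
finally combines criterion statuses into an overall verdict.

Missing observations and indeterminate variables evaluate to *unknown*,
propagated under Kleene's strong three-valued logic: ``and(false, unknown)``
is false, ``or(true, unknown)`` is true, and everything a missing value could
still sway stays unknown.  An unknown verdict therefore means "needs human
review", never a silent exclusion.
"""

from __future__ import annotations

import enum
from collections import defaultdict
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
    topological_order,
)

__all__ = [
    "UNKNOWN",
    "TriValue",
    "tri_and",
    "tri_or",
    "tri_not",
    "Observation",
    "Note",
    "PatientRecord",
    "EligibilityVerdict",
    "CriterionOutcome",
    "EvaluationError",
    "aggregate_observations",
    "evaluate_variable",
    "evaluate_criterion",
    "evaluate_trial",
]

DAYS_PER_MONTH = 30.4375  # mean Gregorian month; calendar months not used


class _Unknown:
    """Singleton marker for an absent or indeterminate data value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNKNOWN"

    def __bool__(self) -> bool:
        raise TypeError("UNKNOWN has no boolean value; use TriValue")


UNKNOWN = _Unknown()


class TriValue(str, enum.Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    @classmethod
    def of(cls, value) -> "TriValue":
        if value is UNKNOWN:
            return cls.UNKNOWN
        return cls.TRUE if value else cls.FALSE


def tri_and(*vals: TriValue) -> TriValue:
    if any(v is TriValue.FALSE for v in vals):
        return TriValue.FALSE
    if any(v is TriValue.UNKNOWN for v in vals):
        return TriValue.UNKNOWN
    return TriValue.TRUE


def tri_or(*vals: TriValue) -> TriValue:
    if any(v is TriValue.TRUE for v in vals):
        return TriValue.TRUE
    if any(v is TriValue.UNKNOWN for v in vals):
        return TriValue.UNKNOWN
    return TriValue.FALSE


def tri_not(v: TriValue) -> TriValue:
    if v is TriValue.UNKNOWN:
        return TriValue.UNKNOWN
    return TriValue.FALSE if v is TriValue.TRUE else TriValue.TRUE


class EvaluationError(ValueError):
    def __init__(self, code: str, message: str, subject_id: str = ""):
        self.code = code
        self.subject_id = subject_id
        super().__init__(f"{code}: {message}" + (f" ({subject_id})" if subject_id else ""))


# --------------------------------------------------------------------------
# Patient data
# --------------------------------------------------------------------------


@dataclass
class Observation:
    variable_id: str
    value: object
    observed_at: Optional[datetime] = None  # defaults to the note timestamp
    needs_human: bool = False  # mandatory for indeterminate payloads
    note_id: Optional[str] = None  # filled in when flattened from a note


@dataclass
class Note:
    note_id: str
    timestamp: Optional[datetime]
    observations: list[Observation] = field(default_factory=list)


@dataclass
class PatientRecord:
    patient_id: str
    notes: list[Note] = field(default_factory=list)

    def observations_for(self, variable_id: str) -> list[Observation]:
        """All observations of one variable, note order preserved."""
        out: list[Observation] = []
        for note in self.notes:
            for obs in note.observations:
                if obs.variable_id == variable_id:
                    o = Observation(
                        obs.variable_id,
                        obs.value,
                        obs.observed_at or note.timestamp,
                        obs.needs_human,
                        note.note_id,
                    )
                    out.append(o)
        return out


@dataclass
class CriterionOutcome:
    criterion_id: str
    status: TriValue
    trace: dict  # var_id -> {"value": ..., "note_ids": [...]}


@dataclass
class EligibilityVerdict:
    patient_id: str
    overall: TriValue
    per_criterion: list[CriterionOutcome]


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------

_TIME_BASED = (
    AggregationStrategy.EARLIEST_OCCURRENCE,
    AggregationStrategy.LATEST_OCCURRENCE,
    AggregationStrategy.MOST_RECENT,
)


def _pick(observations: list[Observation], strategy: AggregationStrategy):
    """Collapse one group of observations to a single value."""
    if strategy in _TIME_BASED and any(o.observed_at is None for o in observations):
        raise EvaluationError(
            "NO_TIMESTAMP",
            f"strategy {strategy.value} needs timestamps on every observation",
            observations[0].variable_id,
        )
    if strategy is AggregationStrategy.FIRST_VALUE:
        return observations[0].value
    if strategy is AggregationStrategy.LAST_VALUE:
        return observations[-1].value
    if strategy is AggregationStrategy.EARLIEST_OCCURRENCE:
        # the earliest date at which the variable was observed
        return min(o.observed_at for o in observations)
    if strategy is AggregationStrategy.LATEST_OCCURRENCE:
        return max(o.observed_at for o in observations)
    if strategy is AggregationStrategy.MOST_RECENT:
        best = max(enumerate(observations), key=lambda io: (io[1].observed_at, io[0]))
        return best[1].value
    if strategy is AggregationStrategy.MOST_FREQUENT:
        counts: dict = defaultdict(int)
        first_seen: dict = {}
        for idx, o in enumerate(observations):
            counts[o.value] += 1
            key = (o.observed_at or datetime.max, idx)
            if o.value not in first_seen or key < first_seen[o.value]:
                first_seen[o.value] = key
        top = max(counts.values())
        # tie-break: the value whose earliest observation is older
        tied = [v for v, c in counts.items() if c == top]
        return min(tied, key=lambda v: first_seen[v])
    raise EvaluationError("BAD_STRATEGY", f"unknown strategy {strategy!r}")


def aggregate_observations(
    observations: list[Observation],
    scope: Scope,
    strategy: AggregationStrategy = AggregationStrategy.MOST_RECENT,
):
    """Collapse a variable's observations according to its scope.

    many_per_note keeps every value (a list in note-stream order);
    one_per_note applies the strategy within each note and returns one value
    per note; one_per_patient applies it across all notes and returns a
    single value.  No observations at all yield ``UNKNOWN``.
    """
    if not observations:
        return UNKNOWN
    if scope is Scope.MANY_PER_NOTE:
        return [o.value for o in observations]
    if scope is Scope.ONE_PER_NOTE:
        by_note: dict = {}
        order: list = []
        for o in observations:
            if o.note_id not in by_note:
                by_note[o.note_id] = []
                order.append(o.note_id)
            by_note[o.note_id].append(o)
        return [_pick(by_note[nid], strategy) for nid in order]
    if scope is Scope.ONE_PER_PATIENT:
        return _pick(observations, strategy)
    raise EvaluationError("BAD_SCOPE", f"unknown scope {scope!r}")


# --------------------------------------------------------------------------
# Typed expression evaluation with unknown propagation
# --------------------------------------------------------------------------

_PY_TYPES = {
    DataType.INTEGER: (int,),
    DataType.FLOAT: (int, float),
    DataType.BOOLEAN: (bool,),
    DataType.TIMESTAMP: (datetime,),
    DataType.TEXT: (str,),
}


def _check_value_type(value, data_type: DataType, variable_id: str) -> None:
    if value is UNKNOWN or data_type is DataType.INDETERMINATE:
        return
    allowed = _PY_TYPES[data_type]
    ok = isinstance(value, allowed)
    if ok and data_type in (DataType.INTEGER, DataType.FLOAT) and isinstance(value, bool):
        ok = False
    if not ok:
        raise EvaluationError(
            "TYPE_MISMATCH",
            f"value {value!r} does not match declared type {data_type.value}",
            variable_id,
        )


def _as_tri(v) -> TriValue:
    if v is UNKNOWN:
        return TriValue.UNKNOWN
    if isinstance(v, bool):
        return TriValue.of(v)
    raise EvaluationError("TYPE_MISMATCH", f"expected boolean, got {v!r}")


_CMP = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}


def _eval_expr(node: LogicNode, env: dict, owner_id: str):
    """Evaluate one expression node; ``UNKNOWN`` poisons everything except
    and/or, which resolve early when one operand already determines them."""
    op = node.op
    if op == "lit":
        return node.value
    if op == "var":
        return env[node.var_id]
    if op == "not":
        return {
            TriValue.TRUE: False,
            TriValue.FALSE: True,
            TriValue.UNKNOWN: UNKNOWN,
        }[_as_tri(_eval_expr(node.args[0], env, owner_id))]
    if op in ("and", "or"):
        vals = [_as_tri(_eval_expr(a, env, owner_id)) for a in node.args]
        tri = tri_and(*vals) if op == "and" else tri_or(*vals)
        return UNKNOWN if tri is TriValue.UNKNOWN else tri is TriValue.TRUE
    if op == "count":
        v = _eval_expr(node.args[0], env, owner_id)
        if v is UNKNOWN:
            return UNKNOWN
        return len(v) if isinstance(v, list) else 1
    args = [_eval_expr(a, env, owner_id) for a in node.args]
    if any(a is UNKNOWN for a in args):
        return UNKNOWN
    if op in _CMP:
        a, b = args
        try:
            return bool(_CMP[op](a, b))
        except TypeError:
            raise EvaluationError(
                "TYPE_MISMATCH", f"cannot compare {a!r} and {b!r}", owner_id
            ) from None
    if op == "temporal_gap":
        a, b = args
        if not (isinstance(a, datetime) and isinstance(b, datetime)):
            raise EvaluationError(
                "TYPE_MISMATCH", "temporal_gap needs two timestamps", owner_id
            )
        days = (a - b) / timedelta(days=1)
        return days / DAYS_PER_MONTH if node.unit == "months" else days
    if op in ("add", "sub"):
        a, b = args
        if not all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in args):
            raise EvaluationError(
                "TYPE_MISMATCH", f"arithmetic over non-numbers {args!r}", owner_id
            )
        return a + b if op == "add" else a - b
    raise EvaluationError("UNKNOWN_OP", f"unknown logic op {op!r}", owner_id)


# --------------------------------------------------------------------------
# Variable / criterion / trial evaluation
# --------------------------------------------------------------------------


def evaluate_variable(
    protocol: TrialProtocol,
    variable_id: str,
    record: PatientRecord,
    cache: Optional[dict] = None,
):
    """Resolved value of one variable for one patient (UNKNOWN if missing).

    ``cache`` memoizes already-evaluated variables and doubles as the trace
    source; pass the same dict across calls for one (protocol, record) pair.
    """
    cache = cache if cache is not None else {}
    if variable_id in cache:
        return cache[variable_id]["value"]
    v = protocol.variable(variable_id)
    if v.is_independent:
        obs = record.observations_for(variable_id)
        note_ids = [o.note_id for o in obs]
        if v.data_type is DataType.INDETERMINATE:
            # indeterminate data always needs a human; keep the payloads
            value = UNKNOWN
            cache[variable_id] = {
                "value": value,
                "note_ids": note_ids,
                "payload": [o.value for o in obs],
            }
            return value
        for o in obs:
            _check_value_type(o.value, v.data_type, variable_id)
        value = aggregate_observations(obs, v.scope, v.aggregation)
        cache[variable_id] = {"value": value, "note_ids": note_ids}
        return value
    env = {
        inp: evaluate_variable(protocol, inp, record, cache) for inp in v.inputs
    }
    value = _eval_expr(v.logic, env, variable_id)
    _check_value_type(value, v.data_type, variable_id)
    src = sorted(
        {n for inp in v.inputs for n in cache[inp]["note_ids"] if n is not None}
    )
    cache[variable_id] = {"value": value, "note_ids": src}
    return value


def evaluate_criterion(
    protocol: TrialProtocol, criterion: Criterion, record: PatientRecord
) -> CriterionOutcome:
    """Three-valued status of one criterion plus a per-variable trace."""
    cache: dict = {}
    root_vals = [
        _as_tri(evaluate_variable(protocol, r, record, cache))
        for r in criterion.roots
    ]
    status = tri_and(*root_vals) if criterion.combinator == "all" else tri_or(*root_vals)
    trace = {
        vid: {
            "value": info["value"],
            "note_ids": info["note_ids"],
            **({"payload": info["payload"]} if "payload" in info else {}),
        }
        for vid, info in cache.items()
    }
    return CriterionOutcome(criterion.id, status, trace)


def evaluate_trial(
    protocol: TrialProtocol, record: PatientRecord
) -> EligibilityVerdict:
    """Overall eligibility: all inclusions true and no exclusion triggered.

    An exclusion criterion with status true means the patient is excluded;
    the verdict negates the disjunction of exclusion statuses, so unknown
    exclusions leave an otherwise-eligible patient unknown, not eligible.
    """
    # topological_order raises on cycles before any work is done
    topological_order(protocol)
    outcomes = [evaluate_criterion(protocol, c, record) for c in protocol.criteria]
    inclusion = [
        o.status for o, c in zip(outcomes, protocol.criteria) if c.kind == "inclusion"
    ]
    exclusion = [
        o.status for o, c in zip(outcomes, protocol.criteria) if c.kind == "exclusion"
    ]
    overall = tri_and(
        tri_and(*inclusion) if inclusion else TriValue.TRUE,
        tri_not(tri_or(*exclusion)) if exclusion else TriValue.TRUE,
    )
    return EligibilityVerdict(record.patient_id, overall, outcomes)
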