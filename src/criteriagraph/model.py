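"""Domain model for structured clinical-trial eligibility criteria.

A trial protocol is decomposed into *variables*: independent variables are
discrete units of data extracted from clinical notes (a timestamp, a lab
value, a boolean finding), while dependent variables compute a value from
other variables through a small logic-expression grammar and never read
clinical text themselves.  Because dependents may feed other dependents, a
protocol's variables form a directed acyclic graph; each eligibility
criterion points at one or more boolean-typed root variables and combines
them conjunctively (inclusion) or disjunctively (exclusion) by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import networkx as nx

__all__ = [
    "DataType",
    "Scope",
    "AggregationStrategy",
    "LogicNode",
    "VariableDef",
    "Criterion",
    "TrialProtocol",
    "ValidationFinding",
    "ValidationReport",
    "validate_protocol",
    "dependency_closure",
    "topological_order",
    "CycleError",
]


class DataType(str, enum.Enum):
    """Value type an extracted or computed variable carries.

    ``indeterminate`` marks data that does not fit a standard type (for
    example eligibility judged by clinician intuition); such variables always
    evaluate to *unknown* and their payload is surfaced for human review.
    """

    INTEGER = "integer"
    FLOAT = "float"
    BOOLEAN = "boolean"
    TIMESTAMP = "timestamp"
    TEXT = "text"
    INDETERMINATE = "indeterminate"


class Scope(str, enum.Enum):
    """Granularity at which observations are aggregated across notes."""

    MANY_PER_NOTE = "many_per_note"
    ONE_PER_NOTE = "one_per_note"
    ONE_PER_PATIENT = "one_per_patient"


class AggregationStrategy(str, enum.Enum):
    """Rule collapsing multiple observations of one variable to one value.

    ``most_recent`` (value carried by the newest observation) is the default
    when a protocol does not specify a strategy.
    """

    MOST_FREQUENT = "most_frequent"
    FIRST_VALUE = "first_value"
    LAST_VALUE = "last_value"
    EARLIEST_OCCURRENCE = "earliest_occurrence"
    LATEST_OCCURRENCE = "latest_occurrence"
    MOST_RECENT = "most_recent"


# --------------------------------------------------------------------------
# Logic expressions
# --------------------------------------------------------------------------

#: ops taking boolean operands and producing a boolean
BOOL_OPS = frozenset({"and", "or", "not"})
#: binary comparisons over two same-family operands, producing a boolean
CMP_OPS = frozenset({"eq", "ne", "lt", "le", "gt", "ge"})
#: arithmetic over numbers
ARITH_OPS = frozenset({"add", "sub"})
#: every op the grammar admits
ALL_OPS = BOOL_OPS | CMP_OPS | ARITH_OPS | {"temporal_gap", "count", "lit", "var"}

NUMERIC = (DataType.INTEGER, DataType.FLOAT)


@dataclass(frozen=True)
class LogicNode:
    """One node of a dependent variable's logic expression.

    ``op`` is one of: ``and or not`` (boolean composition), ``eq ne lt le gt
    ge`` (comparisons), ``add sub`` (arithmetic), ``count`` (number of values
    of a list-valued input), ``temporal_gap`` (difference of two timestamps
    in ``unit`` = days or months), ``lit`` (typed constant in ``value`` /
    ``value_type``) and ``var`` (reference to an input variable, ``var_id``).
    """

    op: str
    args: tuple["LogicNode", ...] = ()
    value: object = None
    value_type: Optional[DataType] = None
    var_id: Optional[str] = None
    unit: str = "days"  # temporal_gap only: "days" | "months"

    def iter_nodes(self) -> Iterator["LogicNode"]:
        yield self
        for a in self.args:
            yield from a.iter_nodes()

    def var_refs(self) -> set[str]:
        return {n.var_id for n in self.iter_nodes() if n.op == "var" and n.var_id}


def var(var_id: str) -> LogicNode:
    return LogicNode(op="var", var_id=var_id)


def lit(value: object, value_type: Union[DataType, str]) -> LogicNode:
    return LogicNode(op="lit", value=value, value_type=DataType(value_type))


def _n(op: str, *args: LogicNode, **kw) -> LogicNode:
    return LogicNode(op=op, args=tuple(args), **kw)


# convenience constructors used by fixtures and the generator
def and_(*args: LogicNode) -> LogicNode:
    return _n("and", *args)


def or_(*args: LogicNode) -> LogicNode:
    return _n("or", *args)


def not_(arg: LogicNode) -> LogicNode:
    return _n("not", arg)


def cmp(op: str, left: LogicNode, right: LogicNode) -> LogicNode:
    if op not in CMP_OPS:
        raise ValueError(f"not a comparison op: {op!r}")
    return _n(op, left, right)


def temporal_gap(a: LogicNode, b: LogicNode, unit: str = "days") -> LogicNode:
    return _n("temporal_gap", a, b, unit=unit)


def count(arg: LogicNode) -> LogicNode:
    return _n("count", arg)


# --------------------------------------------------------------------------
# Variables, criteria, protocol
# --------------------------------------------------------------------------


@dataclass
class VariableDef:
    """A unit of computation in the protocol's dependency graph.

    Independent variables carry extraction ``instructions`` plus a scope and
    aggregation strategy; dependent variables carry an ordered ``inputs``
    list and a ``logic`` expression whose result type must equal
    ``data_type``.
    """

    id: str
    name: str
    dependency: str  # "independent" | "dependent"
    data_type: DataType
    scope: Scope = Scope.ONE_PER_PATIENT
    aggregation: AggregationStrategy = AggregationStrategy.MOST_RECENT
    instructions: str = ""
    inputs: tuple[str, ...] = ()
    logic: Optional[LogicNode] = None

    @property
    def is_independent(self) -> bool:
        return self.dependency == "independent"


@dataclass
class Criterion:
    """One eligibility criterion: verbatim text plus its decomposition roots.

    ``combinator`` defaults to ``all`` for inclusion criteria (conjunctive)
    and ``any`` for exclusion criteria (disjunctive), the conventional logic
    of each kind; either may be overridden per criterion.
    """

    id: str
    text: str
    kind: str  # "inclusion" | "exclusion"
    roots: tuple[str, ...]
    combinator: Optional[str] = None  # "all" | "any"; None -> kind default

    def __post_init__(self) -> None:
        if self.combinator is None:
            self.combinator = "all" if self.kind == "inclusion" else "any"
        self.roots = tuple(self.roots)


@dataclass
class TrialProtocol:
    id: str
    name: str
    criteria: list[Criterion] = field(default_factory=list)
    variables: dict[str, VariableDef] = field(default_factory=dict)

    def variable(self, var_id: str) -> VariableDef:
        return self.variables[var_id]

    def graph(self) -> nx.DiGraph:
        """Dependency graph with an edge input -> dependent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for v in self.variables.values():
            for inp in v.inputs:
                if inp in self.variables:
                    g.add_edge(inp, v.id)
        return g


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationFinding:
    severity: str  # "error" | "warning"
    code: str
    message: str
    subject_id: str


class ValidationReport(list):
    """List of findings; a protocol is structurally sound iff no errors."""

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self if f.severity == "error"]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


class CycleError(ValueError):
    """Raised when an operation requiring an acyclic graph meets a cycle."""

    def __init__(self, cycle_ids: list[str]):
        self.cycle_ids = list(cycle_ids)
        super().__init__(f"dependency cycle: {' -> '.join(self.cycle_ids)}")


def infer_type(
    node: LogicNode, input_types: dict[str, DataType]
) -> Optional[DataType]:
    """Result type of an expression, or None if it cannot type-check.

    ``indeterminate`` inputs are admissible in any position (they evaluate to
    unknown at run time).  Variables of list-producing scope are only usable
    under ``count``.
    """
    op = node.op
    if op == "lit":
        return node.value_type
    if op == "var":
        return input_types.get(node.var_id)
    child = [infer_type(a, input_types) for a in node.args]
    if any(c is None for c in child):
        return None
    # indeterminate operands are allowed anywhere; they poison to unknown at
    # evaluation, not to a type error
    if op in BOOL_OPS:
        if all(c in (DataType.BOOLEAN, DataType.INDETERMINATE) for c in child):
            return DataType.BOOLEAN
        return None
    if op in CMP_OPS:
        a, b = child
        if DataType.INDETERMINATE in (a, b):
            return DataType.BOOLEAN
        families = [
            {DataType.INTEGER, DataType.FLOAT},
            {DataType.TIMESTAMP},
            {DataType.TEXT},
            {DataType.BOOLEAN},
        ]
        for fam in families:
            if a in fam and b in fam:
                if fam == {DataType.BOOLEAN} and op not in ("eq", "ne"):
                    return None
                if fam == {DataType.TEXT} and op not in ("eq", "ne"):
                    return None
                return DataType.BOOLEAN
        return None
    if op in ARITH_OPS:
        if all(c in NUMERIC or c is DataType.INDETERMINATE for c in child):
            return (
                DataType.INTEGER
                if all(c is DataType.INTEGER for c in child)
                else DataType.FLOAT
            )
        return None
    if op == "temporal_gap":
        if all(c in (DataType.TIMESTAMP, DataType.INDETERMINATE) for c in child):
            return DataType.FLOAT
        return None
    if op == "count":
        # argument must be a (possibly indeterminate) variable reference; the
        # list-ness comes from the referenced variable's scope, checked below
        return DataType.INTEGER
    return None


def validate_protocol(protocol: TrialProtocol) -> ValidationReport:
    """Structural validation; returns findings, never raises.

    Errors cover dangling references, non-boolean criterion roots, malformed
    independent/dependent shapes, logic type mismatches and dependency
    cycles (code ``CYCLE``, listing the offending ids).  Orphan variables and
    criteria whose closure has no independent variable are warnings only, so
    partially decomposed protocols stay loadable.
    """
    report = ValidationReport()
    err = lambda code, msg, sid: report.append(
        ValidationFinding("error", code, msg, sid)
    )
    warn = lambda code, msg, sid: report.append(
        ValidationFinding("warning", code, msg, sid)
    )

    for v in protocol.variables.values():
        if v.dependency not in ("independent", "dependent"):
            err("BAD_DEPENDENCY", f"unknown dependency {v.dependency!r}", v.id)
            continue
        if v.is_independent:
            if v.inputs:
                err("INDEPENDENT_WITH_INPUTS", "independent variable has inputs", v.id)
            if v.logic is not None:
                err("INDEPENDENT_WITH_LOGIC", "independent variable has logic", v.id)
        else:
            if not v.inputs:
                err("DEPENDENT_WITHOUT_INPUTS", "dependent variable has no inputs", v.id)
            for inp in v.inputs:
                if inp not in protocol.variables:
                    err("UNKNOWN_INPUT", f"input {inp!r} does not resolve", v.id)
            if v.logic is None:
                err("DEPENDENT_WITHOUT_LOGIC", "dependent variable has no logic", v.id)
            else:
                for n in v.logic.iter_nodes():
                    if n.op not in ALL_OPS:
                        err("UNKNOWN_OP", f"unknown logic op {n.op!r}", v.id)
                bad_refs = v.logic.var_refs() - set(v.inputs)
                for r in sorted(bad_refs):
                    err(
                        "VAR_REF_NOT_INPUT",
                        f"logic references {r!r} which is not in inputs",
                        v.id,
                    )
                if not bad_refs and all(
                    n.op in ALL_OPS for n in v.logic.iter_nodes()
                ):
                    in_types = {
                        i: protocol.variables[i].data_type
                        for i in v.inputs
                        if i in protocol.variables
                    }
                    if len(in_types) == len(v.inputs):
                        got = infer_type(v.logic, in_types)
                        if got is None:
                            err("TYPE_ERROR", "logic expression does not type-check", v.id)
                        elif got != v.data_type:
                            err(
                                "RESULT_TYPE_MISMATCH",
                                f"logic yields {got.value}, variable declares "
                                f"{v.data_type.value}",
                                v.id,
                            )

    # cycles
    g = protocol.graph()
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        ids = [e[0] for e in cycle]
        err("CYCLE", f"dependency cycle: {' -> '.join(ids + [ids[0]])}", ids[0])
    # self-loops expressed as inputs=[self] show up via find_cycle too, but a
    # dependent listing itself is worth naming even when other errors mask it
    for v in protocol.variables.values():
        if v.id in v.inputs and not any(
            f.code == "CYCLE" and f.subject_id == v.id for f in report
        ):
            err("CYCLE", f"dependency cycle: {v.id} -> {v.id}", v.id)

    seen_crit: set[str] = set()
    reachable: set[str] = set()
    for c in protocol.criteria:
        if c.id in seen_crit:
            err("DUPLICATE_CRITERION_ID", "criterion id reused", c.id)
        seen_crit.add(c.id)
        if not c.roots:
            err("NO_ROOTS", "criterion has no root variables", c.id)
        if c.kind not in ("inclusion", "exclusion"):
            err("BAD_KIND", f"unknown criterion kind {c.kind!r}", c.id)
        if c.combinator not in ("all", "any"):
            err("BAD_COMBINATOR", f"unknown combinator {c.combinator!r}", c.id)
        n_indep = 0
        for r in c.roots:
            if r not in protocol.variables:
                err("UNKNOWN_ROOT", f"root {r!r} does not resolve", c.id)
                continue
            if protocol.variables[r].data_type != DataType.BOOLEAN:
                err(
                    "ROOT_NOT_BOOLEAN",
                    f"root {r!r} has data_type "
                    f"{protocol.variables[r].data_type.value}",
                    c.id,
                )
        if not cycle and all(r in protocol.variables for r in c.roots):
            ind, dep = dependency_closure(protocol, c)
            reachable |= ind | dep
            n_indep = len(ind)
            if n_indep == 0 and c.roots:
                warn(
                    "NO_INDEPENDENTS",
                    "criterion closure contains no independent variables",
                    c.id,
                )
    for vid in sorted(set(protocol.variables) - reachable):
        warn("ORPHAN", "variable unreachable from any criterion root", vid)
    return report


def dependency_closure(
    protocol: TrialProtocol, criterion: Criterion
) -> tuple[set[str], set[str]]:
    """Unique independent and dependent variable ids reachable from the roots.

    Each variable is counted once no matter how many paths reach it — the
    unique-count rule that keeps a criterion's complexity from inflating when
    an independent variable is reused by several sub-criteria.
    """
    independent: set[str] = set()
    dependent: set[str] = set()
    stack = [r for r in criterion.roots]
    seen: set[str] = set()
    while stack:
        vid = stack.pop()
        if vid in seen:
            continue
        seen.add(vid)
        v = protocol.variables[vid]
        if v.is_independent:
            independent.add(vid)
        else:
            dependent.add(vid)
            stack.extend(v.inputs)
    return independent, dependent


def topological_order(protocol: TrialProtocol) -> list[str]:
    """Deterministic evaluation order: inputs before dependents, ties by id."""
    g = protocol.graph()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise CycleError([e[0] for e in cycle]) from None
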