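"""Criterion and trial complexity scoring.

A criterion's complexity is C = I * 2**D where I is the number of *unique*
independent variables in its dependency closure and D the number of dependent
variables.  Independent variables each demand one retrieval from the notes,
while every dependent variable layers a combination step on top, hence the
multiplicative doubling.  Total trial complexity is the sum of per-criterion
scores; criteria are scored independently, so a variable shared between two
criteria counts in both closures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import Criterion, TrialProtocol, dependency_closure
from .stats import median_iqr

__all__ = [
    "CriterionComplexity",
    "ComplexityReport",
    "ComplexityError",
    "criterion_complexity",
    "trial_complexity",
]


class ComplexityError(ValueError):
    def __init__(self, code: str, message: str, criterion_id: str):
        self.code = code
        self.criterion_id = criterion_id
        super().__init__(f"{code}: {message} (criterion {criterion_id})")


@dataclass(frozen=True)
class CriterionComplexity:
    criterion_id: str
    I: int  # unique independent variables in the closure
    D: int  # dependent variables in the closure
    C: int  # I * 2**D, exact integer


@dataclass(frozen=True)
class ComplexityReport:
    per_criterion: tuple[CriterionComplexity, ...]
    total: int
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    quantile_method: str = "linear"


def criterion_complexity(
    protocol: TrialProtocol, criterion: Criterion
) -> CriterionComplexity:
    """Score one criterion; exact integer arithmetic for any I, D.

    Raises ``ComplexityError`` (code ``NO_INDEPENDENTS``) when the closure
    contains no independent variable: a criterion with no extractable data
    point is meaningless under the framework.
    """
    independent, dependent = dependency_closure(protocol, criterion)
    if not independent:
        raise ComplexityError(
            "NO_INDEPENDENTS",
            "criterion closure contains no independent variables",
            criterion.id,
        )
    i, d = len(independent), len(dependent)
    return CriterionComplexity(criterion.id, i, d, i * 2**d)


def trial_complexity(
    protocol: TrialProtocol, quantile_method: str = "linear"
) -> ComplexityReport:
    """Per-criterion scores in protocol order plus total and quartiles.

    An empty protocol yields total 0 with the summary statistics absent.
    """
    scores = tuple(criterion_complexity(protocol, c) for c in protocol.criteria)
    total = sum(s.C for s in scores)
    if scores:
        med, q1, q3 = median_iqr([s.C for s in scores], method=quantile_method)
    else:
        med = q1 = q3 = None
    return ComplexityReport(scores, total, med, q1, q3, quantile_method)
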