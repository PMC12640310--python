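import pytest

from criteriagraph import worked_examples
from criteriagraph.model import (
    Criterion,
    DataType,
    TrialProtocol,
    VariableDef,
    and_,
    var,
)


def indep(vid, dtype="boolean", **kw):
    return VariableDef(id=vid, name=vid, dependency="independent",
                       data_type=DataType(dtype), **kw)


def dep(vid, inputs, logic=None, dtype="boolean"):
    if logic is None:
        logic = and_(*[var(i) for i in inputs])
    return VariableDef(id=vid, name=vid, dependency="dependent",
                       data_type=DataType(dtype), inputs=tuple(inputs),
                       logic=logic)


def protocol_of(variables, criteria, pid="p"):
    return TrialProtocol(id=pid, name=pid,
                         criteria=list(criteria),
                         variables={v.id: v for v in variables})


@pytest.fixture
def examples():
    return worked_examples()


@pytest.fixture
def diamond():
    """I1 feeds D1 and D2; both feed the root D3."""
    vs = [
        indep("I1"),
        dep("D1", ["I1"]),
        dep("D2", ["I1"]),
        dep("D3", ["D1", "D2"]),
    ]
    crit = Criterion(id="c1", text="diamond criterion.", kind="inclusion",
                     roots=("D3",))
    return protocol_of(vs, [crit])
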