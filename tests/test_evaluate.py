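"""Aggregation, three-valued logic and trial evaluation semantics."""

from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from criteriagraph.evaluate import (
    UNKNOWN,
    EvaluationError,
    Note,
    Observation,
    PatientRecord,
    TriValue,
    aggregate_observations,
    evaluate_criterion,
    evaluate_trial,
    evaluate_variable,
    tri_and,
    tri_not,
    tri_or,
)
from criteriagraph.model import (
    AggregationStrategy as Agg,
    Criterion,
    Scope,
    cmp,
    lit,
    temporal_gap,
    var,
)
from criteriagraph.synth import SynthConfig, generate_patient_records, generate_protocol

from conftest import dep, indep, protocol_of

T0 = datetime(2024, 1, 1)


def obs(value, days, vid="x", note=None):
    return Observation(variable_id=vid, value=value,
                       observed_at=T0 + timedelta(days=days), note_id=note)


class TestAggregation:
    def test_most_recent_latest_timestamp_wins(self):
        out = aggregate_observations(
            [obs(True, 1), obs(True, 2), obs(False, 3)],
            Scope.ONE_PER_PATIENT, Agg.MOST_RECENT)
        assert out is False

    def test_most_frequent_modal_value(self):
        out = aggregate_observations(
            [obs("A", 1), obs("A", 2), obs("B", 3)],
            Scope.ONE_PER_PATIENT, Agg.MOST_FREQUENT)
        assert out == "A"

    def test_most_frequent_tie_breaks_to_older_first_observation(self):
        for order in ([obs("A", 1), obs("B", 2)], [obs("B", 2), obs("A", 1)]):
            out = aggregate_observations(
                order, Scope.ONE_PER_PATIENT, Agg.MOST_FREQUENT)
            assert out == "A"

    def test_empty_is_unknown(self):
        assert aggregate_observations([], Scope.ONE_PER_PATIENT,
                                      Agg.MOST_RECENT) is UNKNOWN

    def test_first_and_last_value_use_stream_order(self):
        stream = [obs(10, 5), obs(20, 1), obs(30, 9)]
        assert aggregate_observations(stream, Scope.ONE_PER_PATIENT,
                                      Agg.FIRST_VALUE) == 10
        assert aggregate_observations(stream, Scope.ONE_PER_PATIENT,
                                      Agg.LAST_VALUE) == 30

    def test_earliest_latest_occurrence_return_dates(self):
        stream = [obs(10, 5), obs(20, 1), obs(30, 9)]
        assert aggregate_observations(
            stream, Scope.ONE_PER_PATIENT, Agg.EARLIEST_OCCURRENCE
        ) == T0 + timedelta(days=1)
        assert aggregate_observations(
            stream, Scope.ONE_PER_PATIENT, Agg.LATEST_OCCURRENCE
        ) == T0 + timedelta(days=9)

    def test_many_per_note_keeps_all_values(self):
        stream = [obs(1, 1, note="n1"), obs(2, 1, note="n1"), obs(3, 2, note="n2")]
        assert aggregate_observations(stream, Scope.MANY_PER_NOTE,
                                      Agg.MOST_RECENT) == [1, 2, 3]

    def test_one_per_note_collapses_within_notes(self):
        stream = [obs(1, 1, note="n1"), obs(2, 2, note="n1"),
                  obs(9, 3, note="n2")]
        assert aggregate_observations(stream, Scope.ONE_PER_NOTE,
                                      Agg.MOST_RECENT) == [2, 9]

    def test_missing_timestamp_errors_for_time_based_strategy(self):
        o = Observation(variable_id="x", value=True, observed_at=None)
        with pytest.raises(EvaluationError) as exc:
            aggregate_observations([o], Scope.ONE_PER_PATIENT, Agg.MOST_RECENT)
        assert exc.value.code == "NO_TIMESTAMP"


TRI = [TriValue.TRUE, TriValue.FALSE, TriValue.UNKNOWN]


class TestKleene:
    def test_absorption(self):
        assert tri_and(TriValue.FALSE, TriValue.UNKNOWN) is TriValue.FALSE
        assert tri_or(TriValue.TRUE, TriValue.UNKNOWN) is TriValue.TRUE
        assert tri_or(TriValue.UNKNOWN, TriValue.UNKNOWN) is TriValue.UNKNOWN
        assert tri_not(TriValue.UNKNOWN) is TriValue.UNKNOWN

    @given(st.sampled_from(TRI), st.sampled_from(TRI), st.sampled_from(TRI))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_commutative_associative(self, a, b, c):
        for op in (tri_and, tri_or):
            assert op(a, b) is op(b, a)
            assert op(op(a, b), c) is op(a, op(b, c))

    @given(st.sampled_from(TRI), st.sampled_from(TRI))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_de_morgan(self, a, b):
        assert tri_not(tri_and(a, b)) is tri_or(tri_not(a), tri_not(b))


class TestEvaluateVariable:
    def _gap_protocol(self):
        vs = [
            indep("t_start", "timestamp"),
            indep("t_end", "timestamp"),
            dep("gap_ok", ["t_start", "t_end"],
                logic=cmp("ge",
                          temporal_gap(var("t_end"), var("t_start")),
                          lit(14, "integer"))),
        ]
        crit = Criterion(id="c", text="t.", kind="inclusion", roots=("gap_ok",))
        return protocol_of(vs, [crit])

    def test_temporal_gap_in_days(self):
        p = self._gap_protocol()
        rec = PatientRecord("p1", [Note("n1", T0, [
            Observation("t_start", datetime(2024, 1, 1)),
            Observation("t_end", datetime(2024, 1, 20)),
        ])])
        assert evaluate_variable(p, "gap_ok", rec) is True  # 19-day gap

    def test_temporal_gap_below_threshold(self):
        p = self._gap_protocol()
        rec = PatientRecord("p1", [Note("n1", T0, [
            Observation("t_start", datetime(2024, 1, 1)),
            Observation("t_end", datetime(2024, 1, 10)),
        ])])
        assert evaluate_variable(p, "gap_ok", rec) is False

    def test_unknown_operand_propagates(self):
        p = self._gap_protocol()
        rec = PatientRecord("p1", [Note("n1", T0, [
            Observation("t_start", datetime(2024, 1, 1)),
        ])])
        assert evaluate_variable(p, "gap_ok", rec) is UNKNOWN

    def test_type_mismatch_names_variable(self):
        p = self._gap_protocol()
        rec = PatientRecord("p1", [Note("n1", T0, [
            Observation("t_start", "not-a-date"),
            Observation("t_end", datetime(2024, 1, 20)),
        ])])
        with pytest.raises(EvaluationError) as exc:
            evaluate_variable(p, "gap_ok", rec)
        assert exc.value.code == "TYPE_MISMATCH"
        assert exc.value.subject_id == "t_start"

    def test_indeterminate_always_unknown_with_payload_in_trace(self):
        vs = [indep("gut_feeling", "indeterminate")]
        cache = {}
        rec = PatientRecord("p1", [Note("n1", T0, [
            Observation("gut_feeling", "looks frail")])])
        p = protocol_of(vs, [])
        assert evaluate_variable(p, "gut_feeling", rec, cache) is UNKNOWN
        assert cache["gut_feeling"]["payload"] == ["looks frail"]


class TestCriterionAndTrial:
    def _bool_protocol(self):
        vs = [indep("a"), indep("b"), indep("c")]
        crits = [
            Criterion(id="inc", text="t.", kind="inclusion", roots=("a", "b")),
            Criterion(id="exc", text="t.", kind="exclusion", roots=("c",)),
        ]
        return protocol_of(vs, crits)

    @staticmethod
    def _record(**values):
        return PatientRecord("p1", [Note("n1", T0, [
            Observation(k, v) for k, v in values.items()])])

    def test_inclusion_all_true(self):
        p = self._bool_protocol()
        out = evaluate_criterion(p, p.criteria[0], self._record(a=True, b=True))
        assert out.status is TriValue.TRUE
        assert set(out.trace) == {"a", "b"}

    def test_exclusion_any_with_unknown(self):
        vs = [indep("a"), indep("b")]
        crit = Criterion(id="e", text="t.", kind="exclusion", roots=("a", "b"))
        p = protocol_of(vs, [crit])
        out = evaluate_criterion(p, crit, self._record(a=False))
        assert out.status is TriValue.UNKNOWN

    def test_eligible_patient(self):
        p = self._bool_protocol()
        v = evaluate_trial(p, self._record(a=True, b=True, c=False))
        assert v.overall is TriValue.TRUE

    def test_triggered_exclusion_makes_ineligible(self):
        p = self._bool_protocol()
        v = evaluate_trial(p, self._record(a=True, b=True, c=True))
        assert v.overall is TriValue.FALSE

    def test_failed_inclusion_dominates_unknowns(self):
        p = self._bool_protocol()
        v = evaluate_trial(p, self._record(a=False))  # b, c unobserved
        assert v.overall is TriValue.FALSE

    def test_unknown_exclusion_keeps_verdict_unknown(self):
        p = self._bool_protocol()
        v = evaluate_trial(p, self._record(a=True, b=True))  # c unobserved
        assert v.overall is TriValue.UNKNOWN

    def test_cardiovascular_hierarchy_all_clear(self, examples):
        """With no cardiac findings the exclusion is not triggered."""
        ex4 = next(c for c in examples.criteria if c.id == "ex4")
        rec = self._record(
            mi_recent=False, unstable_angina_recent=False,
            ventricular_arrhythmia_hx=False, av_block_or_med_arrhythmia=False,
            qt_prolongation_hx=False, nyha_class=1, lvef_percent=60.0,
        )
        out = evaluate_criterion(examples, ex4, rec)
        assert out.status is TriValue.FALSE  # exclusion not triggered

    def test_determinism(self):
        cfg = SynthConfig(n_criteria=4, seed=11, missingness_rate=0.3)
        p = generate_protocol(cfg)
        rec = generate_patient_records(p, 1, cfg)[0]
        v1, v2 = evaluate_trial(p, rec), evaluate_trial(p, rec)
        assert v1 == v2

    def test_monotone_information_under_most_recent(self):
        """Prepending strictly older observations never flips a determined
        boolean under most_recent aggregation."""
        vs = [indep("a")]
        crit = Criterion(id="i", text="t.", kind="inclusion", roots=("a",))
        p = protocol_of(vs, [crit])
        newer = Note("n2", T0 + timedelta(days=10),
                     [Observation("a", True)])
        rec = PatientRecord("p1", [newer])
        before = evaluate_trial(p, rec).overall
        older = Note("n1", T0, [Observation("a", False)])
        rec2 = PatientRecord("p1", [older, newer])
        assert evaluate_trial(p, rec2).overall is before is TriValue.TRUE
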