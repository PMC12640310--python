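"""Generator contracts: validity, determinism, calibrated composition."""

import pytest

from criteriagraph.evaluate import TriValue, evaluate_trial
from criteriagraph.io_cli import serialize_protocol
from criteriagraph.model import validate_protocol
from criteriagraph.synth import (
    SynthConfig,
    brute_force_eligibility,
    generate_patient_records,
    generate_protocol,
)


class TestGenerateProtocol:
    def test_forced_minimal_shape(self):
        cfg = SynthConfig(n_criteria=1, independent_count_distribution={1: 1},
                          dependent_fraction=0.0, seed=7)
        p = generate_protocol(cfg)
        assert len(p.criteria) == 1 and len(p.variables) == 1
        v = next(iter(p.variables.values()))
        assert v.is_independent and v.data_type.value == "boolean"
        assert p.criteria[0].roots == (v.id,)

    def test_seed_determinism_bytes(self):
        a = generate_protocol(SynthConfig(seed=5))
        b = generate_protocol(SynthConfig(seed=5))
        assert serialize_protocol(a) == serialize_protocol(b)
        c = generate_protocol(SynthConfig(seed=6))
        assert serialize_protocol(a) != serialize_protocol(c)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_generated_protocols_validate_clean(self, seed):
        p = generate_protocol(SynthConfig(seed=seed))
        rep = validate_protocol(p)
        assert rep.ok, rep.errors[:3]

    def test_dependent_share_tracks_target(self):
        """Default 18% dependent share held to within 5 percentage points
        pooled over seeds 1-20."""
        dep = tot = 0
        for seed in range(1, 21):
            p = generate_protocol(SynthConfig(seed=seed))
            for v in p.variables.values():
                tot += 1
                dep += v.dependency == "dependent"
        assert abs(dep / tot - 29 / 160) < 0.05

    def test_infeasible_config_rejected(self):
        cfg = SynthConfig(independent_count_distribution={0: 1},
                          dependent_fraction=0.2)
        with pytest.raises(ValueError):
            generate_protocol(cfg)
        with pytest.raises(ValueError):
            generate_protocol(SynthConfig(dependent_fraction=0.9))

    def test_complexity_distribution_right_skewed(self):
        """With dependents present a minority of criteria dominates the
        score: mean exceeds median across seeds."""
        from criteriagraph.complexity import trial_complexity

        n_skewed = 0
        for seed in range(1, 11):
            rep = trial_complexity(generate_protocol(SynthConfig(seed=seed)))
            mean = rep.total / len(rep.per_criterion)
            n_skewed += mean > rep.median
        assert n_skewed >= 9


class TestGeneratePatients:
    def test_zero_missingness_full_coverage(self):
        cfg = SynthConfig(n_criteria=5, missingness_rate=0.0, seed=3)
        p = generate_protocol(cfg)
        rec = generate_patient_records(p, 3, cfg)
        indep = [v.id for v in p.variables.values() if v.is_independent]
        for r in rec:
            seen = {o.variable_id for n in r.notes for o in n.observations}
            assert set(indep) <= seen

    def test_total_missingness_everything_unknown(self):
        cfg = SynthConfig(n_criteria=4, missingness_rate=1.0, seed=3)
        p = generate_protocol(cfg)
        for r in generate_patient_records(p, 2, cfg):
            assert evaluate_trial(p, r).overall is TriValue.UNKNOWN

    def test_empirical_missingness_concentrates(self):
        cfg = SynthConfig(n_criteria=10, missingness_rate=0.3, seed=9)
        p = generate_protocol(cfg)
        recs = generate_patient_records(p, 200, cfg)
        indep = [v.id for v in p.variables.values() if v.is_independent]
        missing = total = 0
        for v in indep:
            for r in recs:
                total += 1
                missing += not any(
                    o.variable_id == v for n in r.notes for o in n.observations
                )
        assert abs(missing / total - 0.3) < 0.07

    def test_note_timestamps_strictly_increase(self):
        cfg = SynthConfig(n_criteria=3, seed=4)
        p = generate_protocol(cfg)
        for r in generate_patient_records(p, 5, cfg):
            ts = [n.timestamp for n in r.notes]
            assert all(a < b for a, b in zip(ts, ts[1:]))


class TestBruteForceOracle:
    def test_refuses_large_protocols(self):
        p = generate_protocol(SynthConfig(seed=1))  # Trial-A scale
        assert len(p.variables) > 20
        from criteriagraph.evaluate import PatientRecord

        with pytest.raises(ValueError):
            brute_force_eligibility(p, PatientRecord("p", []))

    def test_negation_chain(self):
        from criteriagraph.model import Criterion, not_, var
        from criteriagraph.evaluate import Note, Observation, PatientRecord
        from datetime import datetime

        from conftest import dep, indep, protocol_of

        p = protocol_of(
            [indep("I1"), dep("D1", ["I1"], logic=not_(var("I1")))],
            [Criterion(id="c", text="t.", kind="inclusion", roots=("D1",))],
        )
        rec = PatientRecord("p1", [Note("n1", datetime(2024, 1, 1),
                                        [Observation("I1", True)])])
        assert brute_force_eligibility(p, rec).overall is TriValue.FALSE

    def test_agreement_with_engine_small_sweep(self):
        """Spot equivalence here; the full 500-pair sweep runs in the
        acceptance suite."""
        agreed = 0
        for seed in range(1, 41):
            cfg = SynthConfig(
                n_criteria=3,
                independent_count_distribution={1: 3, 2: 3, 3: 1},
                missingness_rate=0.3, seed=seed)
            p = generate_protocol(cfg)
            if len(p.variables) > 12:
                continue
            for r in generate_patient_records(p, 2, cfg):
                a, b = evaluate_trial(p, r), brute_force_eligibility(p, r)
                assert a.overall is b.overall
                assert [o.status for o in a.per_criterion] == [
                    o.status for o in b.per_criterion]
                agreed += 1
        assert agreed >= 50
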