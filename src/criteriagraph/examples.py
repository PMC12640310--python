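"""A worked example protocol: five breast-cancer trial criteria.

These five criteria span the range of decomposition shapes seen in practice:
a single boolean extraction, a flat conjunction of extractions, a temporal
two-stage check, and two multi-sub-criterion hierarchies (one of which reuses
four of its independent variables on multiple paths).  Their complexity
scores are 1, 3, 8, 56 and 64 respectively, and they double as fixtures for
the readability, evaluation and reporting layers.
"""

from __future__ import annotations

from datetime import datetime

from .model import (
    AggregationStrategy,
    Criterion,
    DataType,
    Scope,
    TrialProtocol,
    VariableDef,
    and_,
    cmp,
    lit,
    not_,
    or_,
    temporal_gap,
    var,
)

__all__ = ["worked_examples", "EXAMPLE_COMPLEXITIES"]

#: expected complexity score per example criterion id
EXAMPLE_COMPLEXITIES = {"ex1": 1, "ex2": 3, "ex3": 8, "ex4": 56, "ex5": 64}


def _indep(vid, name, dtype, scope=Scope.ONE_PER_PATIENT,
           agg=AggregationStrategy.MOST_RECENT, instructions=""):
    return VariableDef(
        id=vid, name=name, dependency="independent", data_type=DataType(dtype),
        scope=scope, aggregation=agg, instructions=instructions,
    )


def _dep(vid, name, inputs, logic, dtype="boolean"):
    return VariableDef(
        id=vid, name=name, dependency="dependent", data_type=DataType(dtype),
        inputs=tuple(inputs), logic=logic,
    )


def _gap_months(later, earlier):
    return temporal_gap(later, earlier, unit="months")


def worked_examples() -> TrialProtocol:
    """Build the five-criterion example protocol (fresh instance each call)."""
    variables: list[VariableDef] = []
    criteria: list[Criterion] = []

    # -- example 1: one independent, no dependents; C = 1 -----------------
    variables.append(
        _indep("her2_positive_hx", "previously HER2-positive on pathology",
               "boolean", instructions="true if any prior pathology report "
               "documents HER2-positive status")
    )
    criteria.append(
        Criterion(
            id="ex1",
            text="Not previously HER2 + on pathology testing.",
            kind="exclusion",
            roots=("her2_positive_hx",),
        )
    )

    # -- example 2: three independents, no dependents; C = 3 --------------
    variables += [
        _indep("pregnancy_test_positive", "positive serum pregnancy test", "boolean"),
        _indep("breastfeeding", "currently breastfeeding", "boolean"),
        _indep("assigned_female_at_birth", "assigned female at birth", "boolean"),
    ]
    criteria.append(
        Criterion(
            id="ex2",
            text=(
                "Does not have a positive serum pregnancy test and is not "
                "breastfeeding for patients who are assigned female at birth."
            ),
            kind="exclusion",
            roots=(
                "pregnancy_test_positive",
                "breastfeeding",
                "assigned_female_at_birth",
            ),
            combinator="all",
        )
    )

    # -- example 3: two independents, two dependents; C = 2 * 2**2 = 8 ----
    randomization = lit(datetime(2024, 3, 1), "timestamp")
    variables += [
        _indep("last_anticancer_tx_end", "completion date of last anticancer "
               "treatment", "timestamp"),
        _indep("toxicity_resolved", "prior-treatment toxicity resolved or "
               "clinically stable", "boolean"),
        _dep(
            "tx_washout_ok",
            "anticancer treatment completed >= 14 days before randomization",
            ["last_anticancer_tx_end"],
            cmp("ge",
                temporal_gap(randomization, var("last_anticancer_tx_end")),
                lit(14, "integer")),
        ),
        _dep(
            "prior_tx_criterion",
            "washout satisfied and toxicity resolved",
            ["tx_washout_ok", "toxicity_resolved"],
            and_(var("tx_washout_ok"), var("toxicity_resolved")),
        ),
    ]
    criteria.append(
        Criterion(
            id="ex3",
            text=(
                "Patients must have completed any anticancer treatment greater "
                "than or equal to 14 days prior to randomization. Any toxicity "
                "experienced on prior treatment must have resolved or be "
                "considered clinically stable prior to randomization."
            ),
            kind="inclusion",
            roots=("prior_tx_criterion",),
        )
    )

    # -- example 4: seven independents, three sub-criterion dependents;
    #    C = 7 * 2**3 = 56 -------------------------------------------------
    variables += [
        _indep("mi_recent", "myocardial infarction within 6 months of "
               "enrollment", "boolean"),
        _indep("unstable_angina_recent", "unstable angina pectoris within 6 "
               "months of enrollment", "boolean"),
        _indep("ventricular_arrhythmia_hx", "history of serious ventricular "
               "arrhythmia (V-tach or V-fib)", "boolean"),
        _indep("av_block_or_med_arrhythmia", "high-grade AV block or "
               "arrhythmia requiring antiarrhythmics (except controlled "
               "atrial fibrillation)", "boolean"),
        _indep("qt_prolongation_hx", "history of QT interval prolongation",
               "boolean"),
        _indep("nyha_class", "NYHA congestive heart failure class", "integer"),
        _indep("lvef_percent", "left ventricular ejection fraction (%)", "float"),
        _dep(
            "cv_sub_a", "recent MI or unstable angina",
            ["mi_recent", "unstable_angina_recent"],
            or_(var("mi_recent"), var("unstable_angina_recent")),
        ),
        _dep(
            "cv_sub_b", "serious arrhythmia history",
            ["ventricular_arrhythmia_hx", "av_block_or_med_arrhythmia",
             "qt_prolongation_hx"],
            or_(var("ventricular_arrhythmia_hx"),
                var("av_block_or_med_arrhythmia"),
                var("qt_prolongation_hx")),
        ),
        _dep(
            "cv_sub_c", "NYHA class III+ CHF or LVEF < 40%",
            ["nyha_class", "lvef_percent"],
            or_(cmp("ge", var("nyha_class"), lit(3, "integer")),
                cmp("lt", var("lvef_percent"), lit(40.0, "float"))),
        ),
    ]
    criteria.append(
        Criterion(
            id="ex4",
            text=(
                "Patient must not have a history of significant cardiovascular "
                "disease, defined as: a) Myocardial infarction or unstable "
                "angina pectoris within 6 months of enrollment. b) History of "
                "serious ventricular arrhythmia (i.e., ventricular tachycardia "
                "or ventricular fibrillation), high-grade atrioventricular "
                "block, or other cardiac arrhythmias requiring antiarrhythmic "
                "medications (except for atrial fibrillation that is well "
                "controlled with antiarrhythmic medication); history of QT "
                "interval prolongation. c) New York Heart Association Class "
                "III or greater congestive heart failure or known left "
                "ventricular ejection fraction of < 40%."
            ),
            kind="exclusion",
            roots=("cv_sub_a", "cv_sub_b", "cv_sub_c"),
            combinator="any",
        )
    )

    # -- example 5: eight unique independents (four reused across the three
    #    sub-criteria), three dependents; C = 8 * 2**3 = 64 ----------------
    variables += [
        _indep("et_lines_metastatic", "previous lines of endocrine therapy "
               "in the metastatic setting", "integer"),
        _indep("adjuvant_et_start", "start date of adjuvant endocrine "
               "therapy", "timestamp"),
        _indep("recurrence_date", "date of disease recurrence", "timestamp"),
        _indep("progression_on_met_et", "disease progression on metastatic "
               "endocrine therapy", "boolean"),
        _indep("first_line_met_et_start", "start date of first-line "
               "metastatic endocrine therapy", "timestamp"),
        _indep("progression_date", "date of disease progression", "timestamp"),
        _indep("cdk46_received", "CDK 4/6 inhibitor received with endocrine "
               "therapy", "boolean"),
        _indep("et_candidate", "candidate for additional endocrine therapy "
               "in the metastatic setting", "boolean"),
    ]
    recur_on_adjuvant = and_(
        cmp("ge", _gap_months(var("recurrence_date"), var("adjuvant_et_start")),
            lit(0, "integer")),
        cmp("le", _gap_months(var("recurrence_date"), var("adjuvant_et_start")),
            lit(24, "integer")),
    )
    variables += [
        _dep(
            "et_sub_a",
            "progression on >= 2 lines of ET (1 line suffices after early "
            "adjuvant recurrence)",
            ["et_lines_metastatic", "adjuvant_et_start", "recurrence_date",
             "progression_on_met_et"],
            and_(
                var("progression_on_met_et"),
                or_(
                    cmp("ge", var("et_lines_metastatic"), lit(2, "integer")),
                    and_(recur_on_adjuvant,
                         cmp("ge", var("et_lines_metastatic"), lit(1, "integer"))),
                ),
            ),
        ),
        _dep(
            "et_sub_b",
            "progression within 6 months of starting first-line metastatic ET",
            ["et_lines_metastatic", "progression_on_met_et",
             "first_line_met_et_start", "progression_date"],
            and_(
                var("progression_on_met_et"),
                cmp("ge", var("et_lines_metastatic"), lit(1, "integer")),
                cmp("ge", _gap_months(var("progression_date"),
                                      var("first_line_met_et_start")),
                    lit(0, "integer")),
                cmp("le", _gap_months(var("progression_date"),
                                      var("first_line_met_et_start")),
                    lit(6, "integer")),
            ),
        ),
        _dep(
            "et_sub_c",
            "early recurrence on adjuvant ET plus CDK 4/6 inhibitor, no "
            "further ET candidacy",
            ["adjuvant_et_start", "recurrence_date", "cdk46_received",
             "et_candidate"],
            and_(recur_on_adjuvant, var("cdk46_received"),
                 not_(var("et_candidate"))),
        ),
    ]
    criteria.append(
        Criterion(
            id="ex5",
            text=(
                "Patients must have one of the following: a) Disease "
                "progression on greater than or equal to 2 or more previous "
                "lines of ET with or without a targeted therapy in the "
                "metastatic setting. Disease recurrence while on the first 24 "
                "months of starting adjuvant ET will be considered a line of "
                "therapy; these patients will only require 1 line of ET in "
                "the metastatic setting. b) Disease progression within 6 "
                "months of starting first-line ET with or without a CDK 4/6 "
                "inhibitor in the metastatic setting. c) Disease recurrence "
                "while on the first 24 months of starting adjuvant ET with "
                "CDK 4/6 inhibitor and if the patient is no longer a "
                "candidate for additional ET in the metastatic setting."
            ),
            kind="inclusion",
            roots=("et_sub_a", "et_sub_b", "et_sub_c"),
            combinator="any",
        )
    )

    return TrialProtocol(
        id="worked-examples",
        name="Five example criteria from a metastatic breast cancer trial",
        criteria=criteria,
        variables={v.id: v for v in variables},
    )
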