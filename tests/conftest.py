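"""Shared fixtures: the bundled demonstrator dictionary/rule pack and record
builders that answer everything the demonstrator rules need."""

from __future__ import annotations

import pytest

from preopeval.observations import (
    ObservationDef,
    ObservationDictionary,
    PatientRecord,
    SurgicalContext,
)
from preopeval.rules import load_ruleset
from preopeval.scores import _data_path


@pytest.fixture(scope="session")
def ruleset():
    return load_ruleset(_data_path("rulepack.yaml"))


@pytest.fixture(scope="session")
def dictionary(ruleset):
    return ruleset.dictionary


@pytest.fixture
def tiny_dictionary():
    """Three roots, one yes-gated child each plus a grandchild."""
    return ObservationDictionary(
        [
            ObservationDef(id="1", label="root1", value_kind="dichotomous"),
            ObservationDef(id="2", label="root2", value_kind="dichotomous"),
            ObservationDef(id="3", label="root3", value_kind="dichotomous"),
            ObservationDef(id="1.1", label="child", value_kind="dichotomous", parent_id="1"),
            ObservationDef(id="1.1.1", label="grandchild", value_kind="dichotomous", parent_id="1.1"),
            ObservationDef(id="2.1", label="numchild", value_kind="numeric", unit="mg/dL", parent_id="2"),
        ]
    )


def make_record(
    age=70,
    sex="male",
    bmi=26.0,
    asa=3,
    risk="intermediate",
    elective=True,
    answers=None,
    patient_id="T001",
):
    return PatientRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        bmi=bmi,
        asa=asa,
        context=SurgicalContext(risk_class=risk, elective=elective),
        answers=dict(answers or {}),
    )


def full_answers(
    rcri=("no", "no", "no", "no", "no"),
    met=None,
    high_risk_surgery="no",
    osa=("no", "no", "no", "no", "no"),
    renal=("no", "no", "no", "no"),
    charlson=None,
):
    """Answer set covering every observation the demonstrator rules read."""
    answers = {}
    answers["2.2"] = "yes" if "yes" in rcri else "no"
    if "yes" in rcri:
        for obs, v in zip(("2.2.1", "2.2.2", "2.2.3", "2.2.4", "2.2.5"), rcri):
            answers[obs] = v
    if met is None:
        answers["2.1"] = "no"
    else:
        answers["2.1"] = "yes"
        for obs, v in zip(("2.1.4", "2.1.5", "2.1.6"), met):
            answers[obs] = v
    answers["1.1.3"] = high_risk_surgery
    for obs, v in zip(("3.1.1", "3.1.2", "3.1.3", "3.1.4", "3.1.5"), osa):
        answers[obs] = v
    for obs, v in zip(("4.1", "4.2", "4.3", "4.4"), renal):
        answers[obs] = v
    if charlson is not None:
        for i in range(1, 20):
            answers[f"5.{i}"] = charlson.get(f"5.{i}", "no")
    return answers
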