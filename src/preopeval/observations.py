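"""Hierarchical patient observation model.

Findings are stored as typed observations (dichotomous / nominal / numeric)
organised in a forest keyed by dotted identifiers such as ``"2.2.1"``.
Subordinate observations are only *active* — i.e. queried and evaluable —
when their superordinate observation carries a positive (or otherwise
activating) answer, mirroring how structured pre-anaesthesia questionnaires
gate detail questions on screening questions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "MISSING",
    "ObservationDef",
    "ObservationDictionary",
    "SurgicalContext",
    "PatientRecord",
    "Violation",
    "ValidationError",
    "active_observations",
    "set_answer",
    "validate_record",
    "load_dictionary",
    "load_cohort",
]

DICHOTOMOUS_VALUES = ("yes", "no")
RISK_CLASSES = ("low", "intermediate", "high")


class _Missing:
    """Sentinel for an *explicitly* missing answer (distinct from unanswered)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


MISSING = _Missing()


class ValidationError(ValueError):
    """Raised when data violates the observation-model contracts."""


@dataclass(frozen=True)
class Activation:
    """Predicate on the parent's value deciding whether a child is queried.

    ``op`` is one of ``always``, ``is_yes``, ``is_no``, ``equals``, ``in_set``,
    ``lt``, ``le``, ``gt``, ``ge``. ``always`` means the child is active
    whenever its parent is active, regardless of the parent's answer (used for
    purely organisational hierarchy levels).
    """

    op: str = "is_yes"
    value: Any = None

    def matches(self, parent_value: Any) -> bool:
        if self.op == "always":
            return True
        if parent_value is None or parent_value is MISSING:
            return False
        if self.op == "is_yes":
            return parent_value == "yes"
        if self.op == "is_no":
            return parent_value == "no"
        if self.op == "equals":
            return parent_value == self.value
        if self.op == "in_set":
            return parent_value in self.value
        if self.op == "lt":
            return parent_value < self.value
        if self.op == "le":
            return parent_value <= self.value
        if self.op == "gt":
            return parent_value > self.value
        if self.op == "ge":
            return parent_value >= self.value
        raise ValidationError(f"unknown activation op {self.op!r}")


ALWAYS = Activation("always")


@dataclass(frozen=True)
class ObservationDef:
    """One entry of the observation dictionary."""

    id: str
    label: str
    value_kind: str  # dichotomous | nominal | numeric
    allowed_values: tuple[str, ...] | None = None
    unit: str | None = None
    parent_id: str | None = None
    activation: Activation = field(default_factory=Activation)

    def __post_init__(self):
        if self.value_kind not in ("dichotomous", "nominal", "numeric"):
            raise ValidationError(
                f"{self.id}: value_kind must be dichotomous/nominal/numeric, "
                f"got {self.value_kind!r}"
            )
        if self.value_kind == "nominal" and not self.allowed_values:
            raise ValidationError(f"{self.id}: nominal observation needs allowed_values")
        if self.value_kind != "nominal" and self.allowed_values:
            raise ValidationError(f"{self.id}: allowed_values only valid for nominal")
        if self.value_kind != "numeric" and self.unit:
            raise ValidationError(f"{self.id}: unit only valid for numeric")

    def coerce(self, raw: Any) -> Any:
        """Validate and coerce a raw answer to this observation's value kind."""
        if raw is MISSING:
            return MISSING
        if self.value_kind == "dichotomous":
            if raw not in DICHOTOMOUS_VALUES:
                raise ValidationError(
                    f"{self.id}: dichotomous answer must be yes/no, got {raw!r}"
                )
            return raw
        if self.value_kind == "nominal":
            if raw not in self.allowed_values:
                raise ValidationError(
                    f"{self.id}: {raw!r} not in allowed values {self.allowed_values}"
                )
            return raw
        # numeric
        if isinstance(raw, bool) or not isinstance(raw, (int, float, str)):
            raise ValidationError(f"{self.id}: numeric answer expected, got {raw!r}")
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{self.id}: numeric answer expected, got {raw!r}"
            ) from None


class ObservationDictionary:
    """Validated collection of :class:`ObservationDef` forming a forest.

    parent_id is authoritative for the hierarchy; the dotted-prefix rule
    (parent id is a proper dotted prefix of the child id) is *validated*, not
    inferred, so renumbering mistakes surface as errors.
    """

    def __init__(self, defs: Iterable[ObservationDef]):
        self._defs: dict[str, ObservationDef] = {}
        for d in defs:
            if d.id in self._defs:
                raise ValidationError(f"duplicate observation id {d.id!r}")
            self._defs[d.id] = d
        for d in self._defs.values():
            if d.parent_id is not None:
                if d.parent_id not in self._defs:
                    raise ValidationError(
                        f"{d.id}: parent {d.parent_id!r} not in dictionary"
                    )
                if not d.id.startswith(d.parent_id + "."):
                    raise ValidationError(
                        f"{d.id}: parent id {d.parent_id!r} is not a dotted prefix"
                    )
        # forest check: walking parents must terminate without revisiting
        for d in self._defs.values():
            seen = set()
            cur = d
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ValidationError(f"cycle in parent graph at {cur.id!r}")
                seen.add(cur.id)
                cur = self._defs[cur.parent_id]
        self._children: dict[str, list[str]] = {i: [] for i in self._defs}
        for d in self._defs.values():
            if d.parent_id is not None:
                self._children[d.parent_id].append(d.id)

    def __contains__(self, obs_id: str) -> bool:
        return obs_id in self._defs

    def __getitem__(self, obs_id: str) -> ObservationDef:
        return self._defs[obs_id]

    def __iter__(self):
        return iter(self._defs.values())

    def __len__(self):
        return len(self._defs)

    @property
    def ids(self) -> list[str]:
        return list(self._defs)

    def roots(self) -> list[str]:
        return [d.id for d in self._defs.values() if d.parent_id is None]

    def children(self, obs_id: str) -> list[str]:
        return self._children[obs_id]

    def descendants(self, obs_id: str) -> list[str]:
        out = []
        stack = list(self._children[obs_id])
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self._children[i])
        return out


@dataclass(frozen=True)
class SurgicalContext:
    """Planned procedure: 30-day cardiovascular risk class and scheduling."""

    risk_class: str
    elective: bool = True
    procedure_label: str = ""

    def __post_init__(self):
        if self.risk_class not in RISK_CLASSES:
            raise ValidationError(
                f"risk_class must be one of {RISK_CLASSES}, got {self.risk_class!r}"
            )


@dataclass(frozen=True)
class PatientRecord:
    """A patient's demographics, surgical context, and answered observations.

    ``answers`` maps observation id → value; :data:`MISSING` marks a question
    that was asked but could not be answered (distinct from absent = not yet
    asked).
    """

    patient_id: str
    age: int
    sex: str
    bmi: float
    asa: int
    context: SurgicalContext
    answers: Mapping[str, Any] = field(default_factory=dict)

    def answer(self, obs_id: str, default: Any = None) -> Any:
        return self.answers.get(obs_id, default)


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str
    message: str


def active_observations(record: PatientRecord, dictionary: ObservationDictionary) -> set[str]:
    """Return ids whose whole ancestor chain has satisfied activation predicates.

    Roots are always active. A child whose parent is inactive, unanswered, or
    answered so that the activation predicate fails is inactive (subordinate
    findings are only queried on positive superordinate findings).
    """
    for obs_id in record.answers:
        if obs_id not in dictionary:
            raise ValidationError(f"answer refers to unknown observation id {obs_id!r}")
    active: set[str] = set()
    stack = dictionary.roots()
    while stack:
        obs_id = stack.pop()
        active.add(obs_id)
        parent_value = record.answer(obs_id)
        for child in dictionary.children(obs_id):
            act = dictionary[child].activation
            if act.op == "always" or act.matches(parent_value):
                stack.append(child)
    return active


def set_answer(
    record: PatientRecord,
    obs_id: str,
    value: Any,
    dictionary: ObservationDictionary,
) -> PatientRecord:
    """Return a new record with ``obs_id`` answered.

    The observation must currently be active and the value must match its
    kind. If the new value deactivates a subtree, all answers in that subtree
    are cleared so downstream evaluation never sees stale subordinate answers.
    """
    if obs_id not in dictionary:
        raise ValidationError(f"unknown observation id {obs_id!r}")
    if obs_id not in active_observations(record, dictionary):
        raise ValidationError(f"observation {obs_id!r} is not active")
    value = dictionary[obs_id].coerce(value)
    answers = dict(record.answers)
    answers[obs_id] = value
    new = replace(record, answers=answers)
    still_active = active_observations(new, dictionary)
    for desc in dictionary.descendants(obs_id):
        if desc not in still_active:
            answers.pop(desc, None)
    return replace(record, answers=answers)


def validate_record(record: PatientRecord, dictionary: ObservationDictionary) -> list[Violation]:
    """Check the record invariants; violations are returned as data, not raised."""
    out: list[Violation] = []
    if not isinstance(record.age, int) or record.age < 18:
        out.append(Violation("age", "age>=18", f"age must be an integer >= 18, got {record.age!r}"))
    if record.sex not in ("female", "male"):
        out.append(Violation("sex", "sex in {female,male}", f"got {record.sex!r}"))
    if not (isinstance(record.bmi, (int, float)) and record.bmi > 0):
        out.append(Violation("bmi", "bmi>0", f"got {record.bmi!r}"))
    if record.asa not in (3, 4):
        out.append(Violation("asa", "asa in {3,4}", f"got {record.asa!r}"))
    for obs_id, value in record.answers.items():
        if obs_id not in dictionary:
            out.append(Violation(f"answers[{obs_id}]", "known id", "not in dictionary"))
            continue
        try:
            dictionary[obs_id].coerce(value)
        except ValidationError as exc:
            out.append(Violation(f"answers[{obs_id}]", "value kind", str(exc)))
    return out


#: Resolution status of an observation for a given record: ACTIVE (chain of
#: activation predicates satisfied), PENDING (some superordinate gate not yet
#: answered), CLOSED (some superordinate gate answered so the activation
#: predicate definitively fails — the subordinate finding is absent).
ACTIVE, PENDING, CLOSED = "active", "pending", "closed"


def resolution_status(record: PatientRecord, dictionary: ObservationDictionary, obs_id: str) -> str:
    if obs_id not in dictionary:
        raise ValidationError(f"unknown observation id {obs_id!r}")
    chain = []
    cur = dictionary[obs_id]
    while cur.parent_id is not None:
        chain.append(cur)
        cur = dictionary[cur.parent_id]
    status = ACTIVE
    for node in reversed(chain):  # root-most gate first
        if node.activation.op == "always":
            continue
        if status != ACTIVE:
            return status
        parent_value = record.answer(node.parent_id)
        if parent_value is None or parent_value is MISSING:
            status = PENDING
        elif not node.activation.matches(parent_value):
            status = CLOSED
    return status


def resolved_value(record: PatientRecord, dictionary: ObservationDictionary, obs_id: str) -> Any:
    """The value evaluation should see for ``obs_id``.

    ACTIVE → the stored answer (or MISSING if unanswered); PENDING → MISSING;
    CLOSED → the finding is definitively absent, so a dichotomous observation
    resolves to ``"no"`` (nominal/numeric observations have no absent-value
    analogue and stay MISSING). Stored answers on non-active observations are
    never read, so evaluation is invariant to stale values there.
    """
    status = resolution_status(record, dictionary, obs_id)
    if status == ACTIVE:
        value = record.answer(obs_id)
        return MISSING if value is None else value
    if status == CLOSED and dictionary[obs_id].value_kind == "dichotomous":
        return "no"
    return MISSING


def pending_inputs(
    record: PatientRecord, dictionary: ObservationDictionary, obs_ids: Iterable[str]
) -> set[str]:
    """Observations to answer next so that every id in ``obs_ids`` resolves.

    For a PENDING observation this is its first unanswered superordinate gate;
    for an ACTIVE unanswered one, the observation itself. CLOSED dichotomous
    observations resolve to "no" and need nothing.
    """
    out: set[str] = set()
    for obs_id in obs_ids:
        status = resolution_status(record, dictionary, obs_id)
        if status == ACTIVE:
            if record.answer(obs_id) is None or record.answer(obs_id) is MISSING:
                out.add(obs_id)
        elif status == PENDING:
            cur = dictionary[obs_id]
            gates = []
            while cur.parent_id is not None:
                if cur.activation.op != "always":
                    gates.append(cur.parent_id)
                cur = dictionary[cur.parent_id]
            for gate in reversed(gates):
                v = record.answer(gate)
                if v is None or v is MISSING:
                    out.add(gate)
                    break
    return out


# ---------------------------------------------------------------------------
# loaders


def _activation_from_spec(spec: Any) -> Activation:
    if spec is None:
        return Activation()
    if spec == "always":
        return ALWAYS
    if isinstance(spec, dict):
        op = spec.get("op")
        value = spec.get("value")
        if isinstance(value, list):
            value = tuple(value)
        return Activation(op=op, value=value)
    raise ValidationError(f"bad activation spec {spec!r}")


def load_dictionary(source: str | Path | list) -> ObservationDictionary:
    """Load an observation dictionary from YAML/JSON (path or parsed list)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
    else:
        data = source
    if isinstance(data, dict) and "observations" in data:
        data = data["observations"]
    defs = []
    for entry in data:
        allowed = entry.get("allowed_values")
        defs.append(
            ObservationDef(
                id=str(entry["id"]),
                label=entry.get("label", ""),
                value_kind=entry["value_kind"],
                allowed_values=tuple(allowed) if allowed else None,
                unit=entry.get("unit"),
                parent_id=entry.get("parent_id"),
                activation=_activation_from_spec(entry.get("activation")),
            )
        )
    return ObservationDictionary(defs)


def _record_from_json_obj(obj: dict, dictionary: ObservationDictionary) -> PatientRecord:
    ctx = obj["context"]
    answers = {}
    for k, v in obj.get("answers", {}).items():
        if k not in dictionary:
            raise ValidationError(f"answer refers to unknown observation id {k!r}")
        answers[k] = dictionary[k].coerce(MISSING if v is None else v)
    return PatientRecord(
        patient_id=str(obj["patient_id"]),
        age=int(obj["age"]),
        sex=obj["sex"],
        bmi=float(obj["bmi"]),
        asa=int(obj["asa"]),
        context=SurgicalContext(
            risk_class=ctx["risk_class"],
            elective=bool(ctx.get("elective", True)),
            procedure_label=ctx.get("procedure_label", ""),
        ),
        answers=answers,
    )


def load_cohort(path: str | Path, dictionary: ObservationDictionary) -> list[PatientRecord]:
    """Load a cohort from JSON (list of nested records) or wide CSV.

    CSV: one row per patient, observation answers in ``obs.<id>`` columns,
    empty cell = unanswered, literal ``missing`` = explicitly missing.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        return [_record_from_json_obj(o, dictionary) for o in data]
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            answers = {}
            for col, raw in row.items():
                if not col.startswith("obs."):
                    continue
                obs_id = col[4:]
                if raw == "" or raw is None:
                    continue
                if obs_id not in dictionary:
                    raise ValidationError(f"unknown observation column {col!r}")
                answers[obs_id] = dictionary[obs_id].coerce(
                    MISSING if raw == "missing" else raw
                )
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    age=int(row["age"]),
                    sex=row["sex"],
                    bmi=float(row["bmi"]),
                    asa=int(row["asa"]),
                    context=SurgicalContext(
                        risk_class=row["risk_class"],
                        elective=row.get("elective", "true").lower() in ("true", "1", "yes"),
                        procedure_label=row.get("procedure_label", ""),
                    ),
                    answers=answers,
                )
            )
    return records
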