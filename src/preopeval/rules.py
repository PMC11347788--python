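"""Declarative guideline rule engine.

Recommendations are encoded as data — dichotomous decision trees or AND/OR
boolean expressions over observations and named risk scores — and evaluated
deterministically with Kleene three-valued logic so that missing answers
propagate as *unknown* rather than being guessed. A rule may carry several
trigger conditions, each annotated with a GRADE class (strength 1/2 ×
evidence quality A/B/C); when several conditions fire, only the one with the
highest GRADE is displayed while all fired conditions remain available.

Rule files are pure data: predicates compare a target against a literal and
derived quantities must be declared scores, which keeps exhaustive
truth-table checking of any rule set feasible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence, Union

import yaml

from .observations import (
    MISSING,
    ObservationDictionary,
    PatientRecord,
    ValidationError,
    active_observations,
    load_dictionary,
    pending_inputs,
    resolved_value,
)

__all__ = [
    "Kleene",
    "Predicate",
    "Atom",
    "AllOf",
    "AnyOf",
    "Not",
    "TreeLeaf",
    "TreeNode",
    "Condition",
    "Rule",
    "RuleSet",
    "RecommendationInstance",
    "ClearanceDecision",
    "IncompleteRecordError",
    "ConfigurationError",
    "GRADE_ORDER",
    "eval_expr",
    "eval_tree",
    "evaluate_rules",
    "select_display",
    "clearance",
    "mandatory_set",
    "load_ruleset",
]


class ConfigurationError(ValueError):
    """Malformed rule set or unresolvable predicate target."""


class IncompleteRecordError(ValueError):
    """Evaluation blocked by unanswered mandatory observations."""

    def __init__(self, blocking: set[str]):
        self.blocking = set(blocking)
        super().__init__(
            "record incomplete; mandatory observations unanswered: "
            + ", ".join(sorted(self.blocking))
        )


class Kleene(enum.Enum):
    """Three-valued truth: missing inputs yield UNKNOWN, never a guess."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"


_K = Kleene

#: GRADE display priority: any strong (1) recommendation outranks any weak (2)
#: one; within strength, evidence quality A > B > C; `none` ranks last.
GRADE_ORDER = {"1A": 0, "1B": 1, "1C": 2, "2A": 3, "2B": 4, "2C": 5, "none": 6}

#: Actions that count as examinations for the clearance decision. `laboratory:`
#: prefixed actions are examinations; `other:` prefixed actions (e.g. a consult
#: or medication change) are measures and do not block clearance.
EXAMINATION_ACTIONS = {
    "ECG",
    "echocardiography",
    "cardiac_stress_test",
    "chest_xray",
    "pulmonary_function",
    "carotid_doppler",
}

_PREDICATE_OPS = ("is_yes", "is_no", "equals", "lt", "le", "gt", "ge", "in_set")


def _is_examination(action: str) -> bool:
    return action in EXAMINATION_ACTIONS or action.startswith("laboratory:")


@dataclass(frozen=True)
class Predicate:
    """Atomic comparison of an observation or score against a literal."""

    target: str
    op: str
    value: Any = None

    def __post_init__(self):
        if self.op not in _PREDICATE_OPS:
            raise ConfigurationError(f"unknown predicate op {self.op!r}")


@dataclass(frozen=True)
class Atom:
    predicate: Predicate


@dataclass(frozen=True)
class AllOf:
    children: tuple["BoolExpr", ...]

    def __post_init__(self):
        if not self.children:
            raise ConfigurationError("all_of needs at least one child")


@dataclass(frozen=True)
class AnyOf:
    children: tuple["BoolExpr", ...]

    def __post_init__(self):
        if not self.children:
            raise ConfigurationError("any_of needs at least one child")


@dataclass(frozen=True)
class Not:
    child: "BoolExpr"


BoolExpr = Union[Atom, AllOf, AnyOf, Not]


@dataclass(frozen=True)
class TreeLeaf:
    fire: bool


@dataclass(frozen=True)
class TreeNode:
    predicate: Predicate
    yes: "DecisionTree"
    no: "DecisionTree"


DecisionTree = Union[TreeLeaf, TreeNode]


@dataclass(frozen=True)
class Condition:
    """One trigger of a rule: an expression or tree plus its GRADE class."""

    logic: BoolExpr | DecisionTree
    grade: str = "none"

    def __post_init__(self):
        if self.grade not in GRADE_ORDER:
            raise ConfigurationError(f"unknown GRADE class {self.grade!r}")


@dataclass(frozen=True)
class Rule:
    rule_id: str
    action: str
    conditions: tuple[Condition, ...]
    source: str = "consensus"

    def __post_init__(self):
        if not self.conditions:
            raise ConfigurationError(f"rule {self.rule_id!r} has no conditions")
        if self.source not in ("ESAIC", "ESC", "DGAI", "consensus"):
            raise ConfigurationError(f"rule {self.rule_id!r}: bad source {self.source!r}")


@dataclass(frozen=True)
class RecommendationInstance:
    """A fired rule: all fired conditions plus the single displayed one."""

    rule_id: str
    action: str
    fired_conditions: tuple[Condition, ...]
    displayed_condition: Condition

    @property
    def grade(self) -> str:
        return self.displayed_condition.grade


@dataclass(frozen=True)
class ClearanceDecision:
    cleared: bool
    required_actions: tuple[str, ...] = ()


class RuleSet:
    """A versioned rule pack bound to an observation dictionary and scores.

    ``scores`` maps a score name to a callable ``f(record) -> value | MISSING``
    exposing ``required_ids(record)`` (the observation ids still needed) via
    the companion mapping ``score_requirements``.
    """

    def __init__(
        self,
        version: str,
        dictionary: ObservationDictionary,
        rules: Sequence[Rule],
        scores: Mapping[str, Callable[[PatientRecord], Any]] | None = None,
        score_requirements: Mapping[str, Callable[[PatientRecord], set[str]]] | None = None,
    ):
        self.version = version
        self.dictionary = dictionary
        self.rules = tuple(rules)
        self.scores = dict(scores or {})
        self.score_requirements = dict(score_requirements or {})
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate rule_ids in rule set")
        for rule in self.rules:
            for cond in rule.conditions:
                for pred in iter_predicates(cond.logic):
                    if pred.target not in dictionary and pred.target not in self.scores:
                        raise ConfigurationError(
                            f"rule {rule.rule_id!r}: unresolvable target {pred.target!r}"
                        )


def iter_predicates(logic: BoolExpr | DecisionTree) -> Iterable[Predicate]:
    if isinstance(logic, Atom):
        yield logic.predicate
    elif isinstance(logic, (AllOf, AnyOf)):
        for child in logic.children:
            yield from iter_predicates(child)
    elif isinstance(logic, Not):
        yield from iter_predicates(logic.child)
    elif isinstance(logic, TreeNode):
        yield logic.predicate
        yield from iter_predicates(logic.yes)
        yield from iter_predicates(logic.no)
    elif isinstance(logic, TreeLeaf):
        return
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown logic node {logic!r}")


# ---------------------------------------------------------------------------
# evaluation


class _EvalContext:
    """Resolves predicate targets against a record; caches score values."""

    def __init__(self, record: PatientRecord, ruleset: RuleSet):
        self.record = record
        self.ruleset = ruleset
        self.active = active_observations(record, ruleset.dictionary)
        self._score_cache: dict[str, Any] = {}

    def resolve(self, target: str) -> Any:
        """Value of an observation or score; MISSING when unavailable."""
        if target in self.ruleset.scores:
            if target not in self._score_cache:
                self._score_cache[target] = self.ruleset.scores[target](self.record)
            return self._score_cache[target]
        if target not in self.ruleset.dictionary:
            raise ConfigurationError(f"unresolvable predicate target {target!r}")
        return resolved_value(self.record, self.ruleset.dictionary, target)

    def blocking_ids(self, target: str) -> set[str]:
        """Observation ids to answer next behind an unknown target."""
        if target in self.ruleset.scores:
            req = self.ruleset.score_requirements.get(target)
            if req is None:
                return set()
            return set(req(self.record))
        return pending_inputs(self.record, self.ruleset.dictionary, [target])


def _value_missing(value: Any) -> bool:
    return value is None or value is MISSING


def eval_predicate(pred: Predicate, ctx: _EvalContext) -> Kleene:
    value = ctx.resolve(pred.target)
    if _value_missing(value):
        return _K.UNKNOWN
    op = pred.op
    if op == "is_yes":
        result = value == "yes"
    elif op == "is_no":
        result = value == "no"
    elif op == "equals":
        result = value == pred.value
    elif op == "in_set":
        result = value in pred.value
    elif op == "lt":
        result = value < pred.value
    elif op == "le":
        result = value <= pred.value
    elif op == "gt":
        result = value > pred.value
    else:  # ge
        result = value >= pred.value
    return _K.TRUE if result else _K.FALSE


def eval_expr(expr: BoolExpr, record: PatientRecord, ruleset: RuleSet) -> Kleene:
    """Kleene evaluation: unknown propagates unless short-circuited."""
    return _eval_expr(expr, _EvalContext(record, ruleset))


def _eval_expr(expr: BoolExpr, ctx: _EvalContext) -> Kleene:
    if isinstance(expr, Atom):
        return eval_predicate(expr.predicate, ctx)
    if isinstance(expr, AllOf):
        saw_unknown = False
        for child in expr.children:
            v = _eval_expr(child, ctx)
            if v is _K.FALSE:
                return _K.FALSE
            saw_unknown |= v is _K.UNKNOWN
        return _K.UNKNOWN if saw_unknown else _K.TRUE
    if isinstance(expr, AnyOf):
        saw_unknown = False
        for child in expr.children:
            v = _eval_expr(child, ctx)
            if v is _K.TRUE:
                return _K.TRUE
            saw_unknown |= v is _K.UNKNOWN
        return _K.UNKNOWN if saw_unknown else _K.FALSE
    if isinstance(expr, Not):
        v = _eval_expr(expr.child, ctx)
        if v is _K.UNKNOWN:
            return _K.UNKNOWN
        return _K.FALSE if v is _K.TRUE else _K.TRUE
    raise ConfigurationError(f"unknown expression node {expr!r}")


def eval_tree(tree: DecisionTree, record: PatientRecord, ruleset: RuleSet) -> Kleene:
    """Walk a dichotomous decision tree; a missing branch predicate → unknown."""
    return _eval_tree(tree, _EvalContext(record, ruleset))


def _eval_tree(tree: DecisionTree, ctx: _EvalContext) -> Kleene:
    node = tree
    while isinstance(node, TreeNode):
        v = eval_predicate(node.predicate, ctx)
        if v is _K.UNKNOWN:
            return _K.UNKNOWN
        node = node.yes if v is _K.TRUE else node.no
    return _K.TRUE if node.fire else _K.FALSE


def _eval_condition(cond: Condition, ctx: _EvalContext) -> Kleene:
    if isinstance(cond.logic, (TreeLeaf, TreeNode)):
        return _eval_tree(cond.logic, ctx)
    return _eval_expr(cond.logic, ctx)


def select_display(fired_conditions: Sequence[Condition]) -> Condition:
    """Pick the condition with the highest GRADE; ties → first declared."""
    if not fired_conditions:
        raise ValueError("select_display requires at least one fired condition")
    return min(fired_conditions, key=lambda c: GRADE_ORDER[c.grade])


def _condition_blocking(cond_logic: BoolExpr | DecisionTree, ctx: _EvalContext) -> set[str]:
    """Observation ids whose absence keeps this condition's value unknown.

    Short-circuited subtrees contribute nothing: atoms of an all_of that is
    already false, or of an any_of that is already true, are not mandatory.
    """
    if isinstance(cond_logic, Atom):
        if eval_predicate(cond_logic.predicate, ctx) is _K.UNKNOWN:
            return ctx.blocking_ids(cond_logic.predicate.target)
        return set()
    if isinstance(cond_logic, AllOf):
        vals = [_eval_expr(c, ctx) for c in cond_logic.children]
        if _K.FALSE in vals:
            return set()
        out: set[str] = set()
        for child, v in zip(cond_logic.children, vals):
            if v is _K.UNKNOWN:
                out |= _condition_blocking(child, ctx)
        return out
    if isinstance(cond_logic, AnyOf):
        vals = [_eval_expr(c, ctx) for c in cond_logic.children]
        if _K.TRUE in vals:
            return set()
        out = set()
        for child, v in zip(cond_logic.children, vals):
            if v is _K.UNKNOWN:
                out |= _condition_blocking(child, ctx)
        return out
    if isinstance(cond_logic, Not):
        return _condition_blocking(cond_logic.child, ctx)
    if isinstance(cond_logic, TreeLeaf):
        return set()
    # TreeNode: walk to the first unknown predicate on the realised path
    v = eval_predicate(cond_logic.predicate, ctx)
    if v is _K.UNKNOWN:
        return ctx.blocking_ids(cond_logic.predicate.target)
    branch = cond_logic.yes if v is _K.TRUE else cond_logic.no
    return _condition_blocking(branch, ctx)


def mandatory_set(record: PatientRecord, ruleset: RuleSet) -> set[str]:
    """Active, unanswered observations still needed to decide every rule.

    Empty iff :func:`evaluate_rules` can run to completion. Observations
    behind rules already decided (fired, or false by short-circuit) are not
    mandatory.
    """
    ctx = _EvalContext(record, ruleset)
    needed: set[str] = set()
    for rule in ruleset.rules:
        values = [_eval_condition(c, ctx) for c in rule.conditions]
        for cond, v in zip(rule.conditions, values):
            if v is _K.UNKNOWN:
                needed |= _condition_blocking(cond.logic, ctx)
    return needed


def evaluate_rules(record: PatientRecord, ruleset: RuleSet) -> list[RecommendationInstance]:
    """Evaluate every rule; deterministic output ordered by (grade, rule_id).

    Raises :class:`IncompleteRecordError` (naming the blocking observations)
    if any condition of any rule is still unknown — the mandatory-field
    mechanism forces completeness instead of guessing.
    """
    ctx = _EvalContext(record, ruleset)
    instances = []
    blocking: set[str] = set()
    for rule in ruleset.rules:
        values = [_eval_condition(c, ctx) for c in rule.conditions]
        unknown = [c for c, v in zip(rule.conditions, values) if v is _K.UNKNOWN]
        if unknown:
            for cond in unknown:
                blocking |= _condition_blocking(cond.logic, ctx)
            continue
        fired = tuple(c for c, v in zip(rule.conditions, values) if v is _K.TRUE)
        if fired:
            instances.append(
                RecommendationInstance(
                    rule_id=rule.rule_id,
                    action=rule.action,
                    fired_conditions=fired,
                    displayed_condition=select_display(fired),
                )
            )
    if blocking:
        raise IncompleteRecordError(blocking)
    instances.sort(key=lambda i: (GRADE_ORDER[i.grade], i.rule_id))
    return instances


def clearance(record: PatientRecord, ruleset: RuleSet) -> ClearanceDecision:
    """Cleared iff no fired rule recommends an examination.

    Non-clearance carries the deduplicated examination list, in the order the
    recommendations are displayed.
    """
    actions: list[str] = []
    for inst in evaluate_rules(record, ruleset):
        if _is_examination(inst.action) and inst.action not in actions:
            actions.append(inst.action)
    if actions:
        return ClearanceDecision(cleared=False, required_actions=tuple(actions))
    return ClearanceDecision(cleared=True)


# ---------------------------------------------------------------------------
# loading (strict: unknown keys are rejected)


def _require_keys(obj: dict, allowed: set[str], required: set[str], where: str) -> None:
    extra = set(obj) - allowed
    if extra:
        raise ConfigurationError(f"{where}: unknown keys {sorted(extra)}")
    missing = required - set(obj)
    if missing:
        raise ConfigurationError(f"{where}: missing keys {sorted(missing)}")


def _parse_predicate(obj: dict, where: str) -> Predicate:
    _require_keys(obj, {"target", "op", "value"}, {"target", "op"}, where)
    value = obj.get("value")
    if isinstance(value, list):
        value = frozenset(value)
    return Predicate(target=str(obj["target"]), op=obj["op"], value=value)


def _parse_expr(obj: dict, where: str) -> BoolExpr:
    kinds = [k for k in ("atom", "all_of", "any_of", "not") if k in obj]
    if len(kinds) != 1:
        raise ConfigurationError(f"{where}: expression needs exactly one of atom/all_of/any_of/not")
    _require_keys(obj, {kinds[0]}, {kinds[0]}, where)
    kind = kinds[0]
    body = obj[kind]
    if kind == "atom":
        return Atom(_parse_predicate(body, f"{where}.atom"))
    if kind == "not":
        return Not(_parse_expr(body, f"{where}.not"))
    children = tuple(
        _parse_expr(c, f"{where}.{kind}[{i}]") for i, c in enumerate(body)
    )
    return AllOf(children) if kind == "all_of" else AnyOf(children)


def _parse_tree(obj: Any, where: str) -> DecisionTree:
    if isinstance(obj, str):
        if obj not in ("fire", "no_fire"):
            raise ConfigurationError(f"{where}: leaf must be fire/no_fire, got {obj!r}")
        return TreeLeaf(fire=obj == "fire")
    _require_keys(obj, {"if", "then", "else"}, {"if", "then", "else"}, where)
    return TreeNode(
        predicate=_parse_predicate(obj["if"], f"{where}.if"),
        yes=_parse_tree(obj["then"], f"{where}.then"),
        no=_parse_tree(obj["else"], f"{where}.else"),
    )


def _parse_condition(obj: dict, where: str) -> Condition:
    _require_keys(
        obj, {"grade", "atom", "all_of", "any_of", "not", "tree"}, set(), where
    )
    grade = obj.get("grade", "none")
    if "tree" in obj:
        if any(k in obj for k in ("atom", "all_of", "any_of", "not")):
            raise ConfigurationError(f"{where}: condition is either a tree or an expression")
        return Condition(logic=_parse_tree(obj["tree"], f"{where}.tree"), grade=grade)
    expr_obj = {k: v for k, v in obj.items() if k != "grade"}
    return Condition(logic=_parse_expr(expr_obj, where), grade=grade)


def load_ruleset(
    source: str | Path | dict,
    dictionary: ObservationDictionary | None = None,
    scores: Mapping[str, Callable] | None = None,
    score_requirements: Mapping[str, Callable] | None = None,
) -> RuleSet:
    """Load a YAML/JSON rule pack.

    ``observations`` may be inline or a path relative to the rule file;
    ``scores`` names must be resolvable by the caller-provided score bindings
    (defaults to the built-in bindings of :mod:`preopeval.scores`).
    """
    base = Path(".")
    if isinstance(source, (str, Path)):
        base = Path(source).parent
        data = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        data = source
    _require_keys(
        data, {"version", "observations", "scores", "rules"}, {"version", "rules"}, "ruleset"
    )
    if dictionary is None:
        obs = data.get("observations")
        if obs is None:
            raise ConfigurationError("ruleset: no observation dictionary provided")
        dictionary = load_dictionary(base / obs if isinstance(obs, str) else obs)
    if scores is None:
        from . import scores as _scores_mod

        declared = data.get("scores", [])
        scores, score_requirements = _scores_mod.default_bindings(declared, dictionary)
    rules = []
    for i, robj in enumerate(data["rules"]):
        where = f"rules[{i}]"
        _require_keys(
            robj, {"rule_id", "action", "source", "conditions"}, {"rule_id", "action", "conditions"}, where
        )
        conditions = tuple(
            _parse_condition(c, f"{where}.conditions[{j}]")
            for j, c in enumerate(robj["conditions"])
        )
        rules.append(
            Rule(
                rule_id=str(robj["rule_id"]),
                action=str(robj["action"]),
                conditions=conditions,
                source=robj.get("source", "consensus"),
            )
        )
    return RuleSet(
        version=str(data["version"]),
        dictionary=dictionary,
        rules=rules,
        scores=scores,
        score_requirements=score_requirements,
    )
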