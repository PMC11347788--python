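"""Rule engine: Kleene evaluation, GRADE display, clearance, truth-table
oracle equivalence on randomly generated rule sets."""

import itertools
import random

import pytest

from preopeval.observations import (
    MISSING,
    ObservationDef,
    ObservationDictionary,
)
from preopeval.rules import (
    AllOf,
    AnyOf,
    Atom,
    Condition,
    ConfigurationError,
    IncompleteRecordError,
    Kleene,
    Not,
    Predicate,
    Rule,
    RuleSet,
    TreeLeaf,
    TreeNode,
    clearance,
    eval_expr,
    eval_tree,
    evaluate_rules,
    load_ruleset,
    mandatory_set,
    select_display,
)

from conftest import full_answers, make_record


def flat_dictionary(k):
    """k root-level dichotomous observations x1..xk (no gating)."""
    return ObservationDictionary(
        [ObservationDef(id=f"x{i}", label="", value_kind="dichotomous") for i in range(k)]
    )


def flat_ruleset(rules, k):
    return RuleSet(version="t", dictionary=flat_dictionary(k), rules=rules)


def atom(i):
    return Atom(Predicate(target=f"x{i}", op="is_yes"))


class TestEvalExpr:
    def test_any_of_met_observations(self, ruleset):
        """OR over the three functional-capacity observations."""
        rec = make_record(answers=full_answers(met=("no", "yes", "no")))
        expr = AnyOf(
            tuple(Atom(Predicate(t, "is_yes")) for t in ("2.1.4", "2.1.5", "2.1.6"))
        )
        assert eval_expr(expr, rec, ruleset) is Kleene.TRUE

    def test_all_of_short_circuits_on_false(self, ruleset):
        rs = flat_ruleset([], 2)
        rec = make_record(answers={"x0": "no"})  # x1 missing
        expr = AllOf((atom(0), atom(1)))
        assert eval_expr(expr, rec, rs) is Kleene.FALSE

    def test_any_of_short_circuits_on_true(self):
        rs = flat_ruleset([], 2)
        rec = make_record(answers={"x0": "yes"})
        assert eval_expr(AnyOf((atom(0), atom(1))), rec, rs) is Kleene.TRUE

    def test_atom_on_missing_observation_is_unknown(self):
        rs = flat_ruleset([], 1)
        rec = make_record(answers={})
        assert eval_expr(atom(0), rec, rs) is Kleene.UNKNOWN
        rec2 = make_record(answers={"x0": MISSING})
        assert eval_expr(atom(0), rec2, rs) is Kleene.UNKNOWN

    def test_not_propagates_unknown(self):
        rs = flat_ruleset([], 1)
        assert eval_expr(Not(atom(0)), make_record(answers={}), rs) is Kleene.UNKNOWN
        assert eval_expr(Not(atom(0)), make_record(answers={"x0": "yes"}), rs) is Kleene.FALSE

    def test_unresolvable_target_is_configuration_error(self):
        rs = flat_ruleset([], 1)
        bad = Atom(Predicate("nope", "is_yes"))
        with pytest.raises(ConfigurationError):
            eval_expr(bad, make_record(answers={}), rs)


class TestEvalTree:
    def test_single_node(self):
        rs = flat_ruleset([], 1)
        tree = TreeNode(Predicate("x0", "is_yes"), TreeLeaf(True), TreeLeaf(False))
        assert eval_tree(tree, make_record(answers={"x0": "yes"}), rs) is Kleene.TRUE
        assert eval_tree(tree, make_record(answers={"x0": "no"}), rs) is Kleene.FALSE
        assert eval_tree(tree, make_record(answers={}), rs) is Kleene.UNKNOWN

    def test_three_level_tree_matches_path_enumeration(self):
        """Engine walk equals explicit path evaluation on all 2^3 inputs."""
        rs = flat_ruleset([], 3)
        tree = TreeNode(
            Predicate("x0", "is_yes"),
            TreeNode(Predicate("x1", "is_yes"), TreeLeaf(True), TreeLeaf(False)),
            TreeNode(Predicate("x2", "is_yes"), TreeLeaf(False), TreeLeaf(True)),
        )
        for bits in itertools.product(["yes", "no"], repeat=3):
            rec = make_record(answers={f"x{i}": b for i, b in enumerate(bits)})
            expected = (
                (bits[0] == "yes" and bits[1] == "yes")
                or (bits[0] == "no" and bits[2] == "no")
            )
            got = eval_tree(tree, rec, rs)
            assert got is (Kleene.TRUE if expected else Kleene.FALSE)


class TestSelectDisplay:
    def test_strong_beats_weak_evidence(self):
        c2b = Condition(atom(0), grade="2B")
        c1c = Condition(atom(1), grade="1C")
        assert select_display([c2b, c1c]) is c1c

    def test_single_condition(self):
        c = Condition(atom(0), grade="2A")
        assert select_display([c]) is c

    def test_tie_broken_by_declaration_order(self):
        c1 = Condition(atom(0), grade="2A")
        c2 = Condition(atom(1), grade="2A")
        assert select_display([c1, c2]) is c1

    def test_empty_is_contract_violation(self):
        with pytest.raises(ValueError):
            select_display([])


class TestDemonstratorRules:
    def stress_record(self, **kw):
        defaults = dict(
            rcri=("yes", "yes", "yes", "no", "no"),
            met=("yes", "no", "no"),
            high_risk_surgery="yes",
            risk="high",
        )
        defaults.update(kw)
        risk = defaults.pop("risk")
        return make_record(risk=risk, answers=full_answers(**defaults))

    def test_stress_test_rule_fires(self, ruleset):
        """3 clinical risk factors + <4 MET + high-risk surgery → stress test."""
        rec = self.stress_record()
        actions = {i.action for i in evaluate_rules(rec, ruleset)}
        assert "cardiac_stress_test" in actions

    def test_stress_test_requires_high_risk_surgery(self, ruleset):
        rec = self.stress_record(high_risk_surgery="no")
        actions = {i.action for i in evaluate_rules(rec, ruleset)}
        assert "cardiac_stress_test" not in actions

    def test_clearance_when_no_rule_fires(self, ruleset):
        rec = make_record(risk="low", age=50, answers=full_answers())
        decision = clearance(rec, ruleset)
        assert decision.cleared and decision.required_actions == ()

    def test_non_clearance_lists_deduplicated_actions(self, ruleset):
        rec = self.stress_record()
        decision = clearance(rec, ruleset)
        assert not decision.cleared
        assert len(decision.required_actions) == len(set(decision.required_actions))
        assert "cardiac_stress_test" in decision.required_actions

    def test_non_examination_action_does_not_block_clearance(self, ruleset):
        """A consult recommendation alone leaves the patient cleared."""
        rec = make_record(
            risk="low",
            age=50,
            sex="female",
            answers=full_answers(rcri=("yes", "yes", "yes", "yes", "no")),
        )
        instances = evaluate_rules(rec, ruleset)
        assert {i.action for i in instances} == {"other:cardiology_consult"}
        assert clearance(rec, ruleset).cleared

    def test_display_grade_never_below_any_fired_grade(self, ruleset):
        from preopeval.rules import GRADE_ORDER

        rec = self.stress_record()
        for inst in evaluate_rules(rec, ruleset):
            assert GRADE_ORDER[inst.grade] == min(
                GRADE_ORDER[c.grade] for c in inst.fired_conditions
            )

    def test_incomplete_record_names_blocking_observations(self, ruleset):
        answers = full_answers(rcri=("yes", "yes", "yes", "no", "no"), met=("yes", "no", "no"))
        del answers["2.2.3"]
        rec = make_record(risk="high", answers=dict(answers, **{"1.1.3": "yes"}))
        with pytest.raises(IncompleteRecordError) as exc:
            evaluate_rules(rec, ruleset)
        assert "2.2.3" in exc.value.blocking

    def test_inactive_answers_do_not_change_output(self, ruleset):
        """Perturbing values behind a closed gate leaves evaluation unchanged."""
        rec = make_record(risk="high", answers=full_answers())
        baseline = evaluate_rules(rec, ruleset)
        perturbed = dict(rec.answers)
        perturbed["2.2.1"] = "yes"  # 2.2 is answered "no": closed subtree
        rec2 = make_record(risk="high", answers=perturbed)
        assert evaluate_rules(rec2, ruleset) == baseline


class TestMandatorySet:
    def test_complete_record_has_empty_mandatory_set(self, ruleset):
        rec = make_record(risk="high", answers=full_answers())
        assert mandatory_set(rec, ruleset) == set()

    def test_undecided_cardiac_rule_requires_missing_item(self, ruleset):
        answers = full_answers(rcri=("yes", "yes", "yes", "no", "no"), met=("yes", "no", "no"))
        del answers["2.2.3"]
        rec = make_record(risk="high", answers=dict(answers, **{"1.1.3": "yes"}))
        assert "2.2.3" in mandatory_set(rec, ruleset)

    def test_short_circuited_rule_frees_its_atoms(self):
        """all_of already false → the unanswered atom is not mandatory."""
        rs = flat_ruleset(
            [Rule("r", "ECG", (Condition(AllOf((atom(0), atom(1))), "1C"),))], 2
        )
        rec = make_record(answers={"x0": "no"})
        assert mandatory_set(rec, rs) == set()

    def test_mandatory_empty_iff_evaluate_runs(self, ruleset):
        answers = full_answers()
        del answers["1.1.3"]
        rec = make_record(risk="high", answers=answers)
        ms = mandatory_set(rec, ruleset)
        if ms:
            with pytest.raises(IncompleteRecordError):
                evaluate_rules(rec, ruleset)
        else:
            evaluate_rules(rec, ruleset)


def random_expr(rng, atoms, depth=0):
    kind = rng.choice(["atom"] if depth >= 3 else ["atom", "all", "any", "not"])
    if kind == "atom":
        return Atom(Predicate(rng.choice(atoms), "is_yes"))
    if kind == "not":
        return Not(random_expr(rng, atoms, depth + 1))
    children = tuple(
        random_expr(rng, atoms, depth + 1) for _ in range(rng.randint(1, 3))
    )
    return AllOf(children) if kind == "all" else AnyOf(children)


def brute_force(expr, assignment):
    """Independent two-valued oracle on a complete assignment."""
    if isinstance(expr, Atom):
        return assignment[expr.predicate.target]
    if isinstance(expr, AllOf):
        return all(brute_force(c, assignment) for c in expr.children)
    if isinstance(expr, AnyOf):
        return any(brute_force(c, assignment) for c in expr.children)
    return not brute_force(expr.child, assignment)


class TestTruthTableOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_engine_equals_truth_table(self, seed):
        """Random rule sets with <=12 atoms vs exhaustive enumeration."""
        rng = random.Random(seed)
        k = rng.randint(2, 6)
        names = [f"x{i}" for i in range(k)]
        rules = [
            Rule(
                rule_id=f"r{j}",
                action="ECG",
                conditions=tuple(
                    Condition(random_expr(rng, names), grade=rng.choice(["1A", "2B", "none"]))
                    for _ in range(rng.randint(1, 2))
                ),
            )
            for j in range(3)
        ]
        rs = flat_ruleset(rules, k)
        for bits in itertools.product([True, False], repeat=k):
            assignment = dict(zip(names, bits))
            rec = make_record(
                answers={n: ("yes" if b else "no") for n, b in assignment.items()}
            )
            fired = {i.rule_id for i in evaluate_rules(rec, rs)}
            expected = {
                r.rule_id
                for r in rules
                if any(brute_force(c.logic, assignment) for c in r.conditions)
            }
            assert fired == expected

    def test_determinism(self, ruleset):
        rec = make_record(
            risk="high",
            answers=full_answers(rcri=("yes", "yes", "yes", "no", "no"), met=("yes", "no", "no"), high_risk_surgery="yes"),
        )
        assert evaluate_rules(rec, ruleset) == evaluate_rules(rec, ruleset)
        grades = [i.grade for i in evaluate_rules(rec, ruleset)]
        from preopeval.rules import GRADE_ORDER

        assert grades == sorted(grades, key=GRADE_ORDER.__getitem__)


class TestLoader:
    def test_unknown_key_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "version: '1'\nbogus: 1\nrules:\n"
            "  - {rule_id: r, action: ECG, conditions: [{atom: {target: x, op: is_yes}}]}\n"
        )
        with pytest.raises(ConfigurationError, match="bogus"):
            load_ruleset(str(bad))

    def test_unknown_grade_rejected(self):
        with pytest.raises(ConfigurationError):
            Condition(atom(0), grade="3C")

    def test_duplicate_rule_ids_rejected(self):
        r = Rule("r", "ECG", (Condition(atom(0), "1C"),))
        with pytest.raises(ConfigurationError, match="duplicate"):
            flat_ruleset([r, r], 1)

    def test_unresolvable_target_rejected(self):
        r = Rule("r", "ECG", (Condition(Atom(Predicate("ghost", "is_yes")), "1C"),))
        with pytest.raises(ConfigurationError, match="ghost"):
            flat_ruleset([r], 1)

    def test_bundled_rulepack_roundtrip(self, ruleset):
        assert len(ruleset.rules) == 7
        assert {r.source for r in ruleset.rules} <= {"ESAIC", "ESC", "DGAI", "consensus"}
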