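"""Rule parsing, three-valued evaluation, classification, and bit patterns."""

from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regefm.network_io import split_reversibles
from regefm.rule_engine import (
    Activity,
    And,
    Not,
    Or,
    RuleAtom,
    RuleClass,
    RuleError,
    classify_rule,
    compile_patterns,
    eval_tribool,
    expr_atoms,
    parse_rule_line,
    parse_rules,
    rule_violated,
)

from conftest import tiny_network

NET = tiny_network(6)  # reactions R1..R6, all irreversible


# ---------------------------------------------------------------------------
# Parsing


def test_parse_not_full_active(fig1_net):
    rule = parse_rule_line("R7r = NOT(fR9)", fig1_net)
    assert rule.output == RuleAtom("R7r", Activity.FULL_ACTIVE)
    assert rule.expr == Not(RuleAtom("R9", Activity.FULL_ACTIVE))


def test_parse_bang_and_parens():
    rule = parse_rule_line("R1 = (!fR5)", NET)
    assert rule.output == RuleAtom("R1", Activity.FULL_ACTIVE)
    assert rule.expr == Not(RuleAtom("R5", Activity.FULL_ACTIVE))


def test_parse_unknown_reaction_rejected(fig1_net):
    with pytest.raises(RuleError, match="unknown reaction"):
        parse_rule_line("R7r = NOT(Rx)", fig1_net)


@pytest.mark.parametrize("bad", ["R1 NOT(R2)", "R1 = AND R2", "R1 = (R2", "R1 = R2)"])
def test_parse_syntax_errors(bad):
    with pytest.raises(RuleError):
        parse_rule_line(bad, NET)


def test_parse_precedence_and_activities():
    rule = parse_rule_line("0R1 = 1R2 OR R3 AND NOT 0R4", NET)
    assert rule.output.activity is Activity.ZERO_ACTIVE
    assert rule.expr == Or(
        RuleAtom("R2", Activity.ONE_ACTIVE),
        And(RuleAtom("R3", Activity.FULL_ACTIVE), Not(RuleAtom("R4", Activity.ZERO_ACTIVE))),
    )


def test_parse_rules_file(tmp_path, fig1_net):
    p = tmp_path / "rules.txt"
    p.write_text("# comment line\nR7r = NOT(fR9)\n\nR3 = fR4\n")
    rules = parse_rules(p, fig1_net)
    assert [r.rule_id for r in rules] == ["GR1", "GR2"]
    assert rules[0].source_text == "R7r = NOT(fR9)"


# ---------------------------------------------------------------------------
# Three-valued evaluation


@pytest.mark.parametrize(
    "expr,assignment,expected",
    [
        (Not(RuleAtom("R9", Activity.ONE_ACTIVE)), {"R9": 0}, None),
        (Not(RuleAtom("R9", Activity.FULL_ACTIVE)), {"R9": 1}, False),
        (And(RuleAtom("R1", Activity.ZERO_ACTIVE), RuleAtom("R2")), {"R1": 1, "R2": 0}, False),
        (And(RuleAtom("R1", Activity.ZERO_ACTIVE), RuleAtom("R2")), {"R1": 1, "R2": 1}, None),
        (Or(RuleAtom("R1", Activity.ONE_ACTIVE), RuleAtom("R2")), {"R1": 0, "R2": 1}, True),
        (Or(RuleAtom("R1", Activity.ONE_ACTIVE), RuleAtom("R2")), {"R1": 0, "R2": 0}, None),
    ],
)
def test_eval_tribool_cases(expr, assignment, expected):
    assert eval_tribool(expr, assignment) is expected


_atoms = st.builds(
    RuleAtom,
    reaction=st.sampled_from(["R1", "R2", "R3"]),
    activity=st.sampled_from(list(Activity)),
)
_exprs = st.recursive(
    _atoms,
    lambda inner: st.one_of(
        st.builds(Not, inner),
        st.builds(And, inner, inner),
        st.builds(Or, inner, inner),
    ),
    max_leaves=6,
)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(expr=_exprs, bits=st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 1)))
def test_kleene_laws(expr, bits):
    """Double negation, De Morgan, and agreement with two-valued logic on
    fully defined inputs."""
    a = dict(zip(["R1", "R2", "R3"], bits))
    v = eval_tribool(expr, a)
    assert eval_tribool(Not(Not(expr)), a) is v
    assert eval_tribool(Not(And(expr, expr)), a) is eval_tribool(Not(expr), a)
    if all(atom.activity is Activity.FULL_ACTIVE for atom in expr_atoms(expr)):
        assert v is not None  # full-active expressions are always defined


@settings(deadline=None, derandomize=True, max_examples=200)
@given(l=_exprs, r=_exprs, bits=st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 1)))
def test_de_morgan(l, r, bits):
    a = dict(zip(["R1", "R2", "R3"], bits))
    assert eval_tribool(Not(And(l, r)), a) is eval_tribool(Or(Not(l), Not(r)), a)


# ---------------------------------------------------------------------------
# Violation and classification


@pytest.mark.parametrize(
    "text,assignment,expected",
    [
        ("R7r = NOT(fR9)", {"R7r": 1, "R9": 1}, True),
        ("R7r = NOT(fR9)", {"R7r": 0, "R9": 0}, True),
        ("R7r = NOT(fR9)", {"R7r": 0, "R9": 1}, False),
        ("R7r = NOT(1R9)", {"R7r": 1, "R9": 1}, True),
        ("R7r = NOT(1R9)", {"R7r": 0, "R9": 0}, False),  # RHS undefined
    ],
)
def test_rule_violated(fig1_net, text, assignment, expected):
    rule = parse_rule_line(text, fig1_net)
    assert rule_violated(rule, assignment) is expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("R1 = NOT(fR2)", RuleClass.ITERATION_PHASE),
        ("R1 = NOT(1R2)", RuleClass.ITERATION_PHASE),
        ("R1 = fR2", RuleClass.POST_ONLY),        # expr true at all-ones
        ("0R1 = NOT(fR2)", RuleClass.POST_ONLY),  # output undefined at flux 1
        ("R1 = NOT(0R2)", RuleClass.POST_ONLY),   # expr undefined at all-ones
        ("R1 = NOT(fR2) AND NOT(fR3)", RuleClass.ITERATION_PHASE),
    ],
)
def test_classify_rule(text, expected):
    assert classify_rule(parse_rule_line(text, NET)) is expected


# ---------------------------------------------------------------------------
# Pattern compilation and soundness


def test_compile_patterns_reversible_output(fig1_net, fig1_ext):
    rule = parse_rule_line("R7r = NOT(fR9)", fig1_net)
    patterns = compile_patterns([rule], fig1_ext)
    names = {
        frozenset(fig1_ext.ext_reaction_ids[i] for i in p.ext_indices())
        for p in patterns
    }
    assert names == {frozenset({"R7f", "R9"}), frozenset({"R7b", "R9"})}


def test_compile_patterns_counts():
    irrev = tiny_network(4)
    ext = split_reversibles(irrev)
    assert len(compile_patterns([parse_rule_line("R1 = NOT(fR3)", irrev)], ext)) == 1

    both_rev = tiny_network(4, reversible=(1, 3))
    ext2 = split_reversibles(both_rev)
    assert len(compile_patterns([parse_rule_line("R1 = NOT(fR3)", both_rev)], ext2)) == 4


def test_post_only_rules_compile_to_nothing(fig1_net, fig1_ext):
    rule = parse_rule_line("R7r = fR9", fig1_net)
    assert compile_patterns([rule], fig1_ext) == []


@pytest.mark.parametrize(
    "text", ["R7r = NOT(fR9)", "R7r = NOT(1R9)", "R3 = NOT(fR4 AND fR7r)"]
)
def test_pattern_soundness_exhaustive(fig1_net, fig1_ext, text):
    """Every support matched by a compiled pattern genuinely violates the
    rule under three-valued evaluation (patterns never over-prune)."""
    rule = parse_rule_line(text, fig1_net)
    patterns = compile_patterns([rule], fig1_ext)
    n = fig1_ext.n_ext
    for support in range(1 << n):
        if not any(support & p.bits == p.bits for p in patterns):
            continue
        assignment = {}
        for j, rid in enumerate(fig1_net.reaction_ids):
            cols = fig1_ext.col_map[rid]
            assignment[rid] = int(any(support >> c & 1 for c in cols))
        assert rule_violated(rule, assignment)
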