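"""Boolean transcriptional-regulatory rules in a three-state activity logic.

A rule line has the form ``Ro = B(R1, ..., Rn)`` where ``B`` is a Boolean
expression over reaction flux states built from NOT/AND/OR.  Every reaction
occurrence carries an *activity* tag deciding when its flux bit is a defined
truth value:

* ``0``-active — defined only while the reaction carries *no* flux,
* ``1``-active — defined only while the reaction carries flux,
* ``f``-ull-active — always defined (the default for untagged occurrences).

An occurrence whose activity condition fails evaluates to *undefined*;
connectives follow Kleene's strong three-valued semantics and a rule whose
output or expression is undefined is simply not consulted.  A mode violates
a rule only when both sides are defined and disagree.

Rules whose expression is definitely *false* once every input reaction
carries flux (and whose output is defined at flux 1) can prune modes during
the double-description iteration: such a mode, and by bitwise-OR monotonicity
every descendant, keeps violating the rule.  These *iteration-phase* rules
are compiled to bit patterns over the extended (split) reaction columns —
one pattern per choice of forward/backward alternative for each reversible
participant — and a mode whose support contains all bits of a pattern is
eliminated.  All rules, iteration-phase or not, are re-checked in
post-processing on the final merged binary modes.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .network_io import ExtendedNetwork, MetabolicNetwork

log = logging.getLogger(__name__)

#: Three-valued truth: True, False, or None for *undefined*.
TriBool = Union[bool, None]


class Activity(enum.Enum):
    ZERO_ACTIVE = "0"
    ONE_ACTIVE = "1"
    FULL_ACTIVE = "f"


class RuleError(ValueError):
    """Raised for unparseable rule text or unknown reaction references."""


@dataclass(frozen=True)
class RuleAtom:
    """One tagged reaction occurrence inside a rule."""

    reaction: str
    activity: Activity = Activity.FULL_ACTIVE

    def value(self, flux_bit: int) -> TriBool:
        """Truth value of this occurrence given the reaction's flux bit."""
        if self.activity is Activity.ONE_ACTIVE and not flux_bit:
            return None
        if self.activity is Activity.ZERO_ACTIVE and flux_bit:
            return None
        return bool(flux_bit)


@dataclass(frozen=True)
class Not:
    operand: "Expr"


@dataclass(frozen=True)
class And:
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Or:
    left: "Expr"
    right: "Expr"


Expr = Union[RuleAtom, Not, And, Or]


def expr_atoms(expr: Expr) -> Iterable[RuleAtom]:
    if isinstance(expr, RuleAtom):
        yield expr
    elif isinstance(expr, Not):
        yield from expr_atoms(expr.operand)
    else:
        yield from expr_atoms(expr.left)
        yield from expr_atoms(expr.right)


@dataclass(frozen=True)
class Rule:
    """A parsed regulatory rule ``output = expr``."""

    output: RuleAtom
    expr: Expr
    source_text: str
    rule_id: str = ""

    def input_reactions(self) -> list[str]:
        """Distinct reactions occurring in the expression, in first-seen order."""
        seen: dict[str, None] = {}
        for atom in expr_atoms(self.expr):
            seen.setdefault(atom.reaction, None)
        return list(seen)

    def involved_reactions(self) -> list[str]:
        """Inputs plus the output reaction, deduplicated."""
        seen = {self.output.reaction: None}
        for rid in self.input_reactions():
            seen.setdefault(rid, None)
        return list(seen)


class RuleClass(enum.Enum):
    ITERATION_PHASE = "iteration_phase"
    POST_ONLY = "post_only"


@dataclass(frozen=True)
class RulePattern:
    """Bit pattern over extended reaction columns compiled from an
    iteration-phase rule; a mode containing every set bit is infeasible."""

    bits: int
    rule_id: str

    def ext_indices(self) -> list[int]:
        return [i for i in range(self.bits.bit_length()) if self.bits >> i & 1]


# ---------------------------------------------------------------------------
# Parsing

_TOKEN = re.compile(r"\s*(\(|\)|=|!|[A-Za-z0-9_]+)")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise RuleError(f"unexpected character {text[pos:].lstrip()[0]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _resolve_atom(token: str, net: MetabolicNetwork) -> RuleAtom:
    ids = set(net.reaction_ids)
    if token in ids:
        return RuleAtom(token, Activity.FULL_ACTIVE)
    if token[:1] in ("0", "1", "f") and token[1:] in ids:
        return RuleAtom(token[1:], Activity(token[0]))
    raise RuleError(f"unknown reaction id: {token!r}")


class _Parser:
    """Recursive-descent parser for NOT/AND/OR expressions.

    Precedence: NOT/! > AND > OR; AND/OR associate to the left.
    """

    def __init__(self, tokens: list[str], net: MetabolicNetwork):
        self.tokens = tokens
        self.net = net
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleError("unexpected end of rule")
        self.pos += 1
        return tok

    def parse_expr(self) -> Expr:
        node = self.parse_term()
        while self.peek() is not None and self.peek().upper() == "OR":
            self.take()
            node = Or(node, self.parse_term())
        return node

    def parse_term(self) -> Expr:
        node = self.parse_factor()
        while self.peek() is not None and self.peek().upper() == "AND":
            self.take()
            node = And(node, self.parse_factor())
        return node

    def parse_factor(self) -> Expr:
        tok = self.take()
        if tok == "!" or tok.upper() == "NOT":
            return Not(self.parse_factor())
        if tok == "(":
            node = self.parse_expr()
            if self.take() != ")":
                raise RuleError("missing closing parenthesis")
            return node
        if tok in (")", "="):
            raise RuleError(f"unexpected token {tok!r}")
        return _resolve_atom(tok, self.net)


def parse_rule_line(text: str, net: MetabolicNetwork, rule_id: str = "") -> Rule:
    tokens = _tokenize(text)
    if "=" not in tokens:
        raise RuleError("rule must have the form 'OUTPUT = EXPR'")
    eq = tokens.index("=")
    if eq != 1:
        raise RuleError("left-hand side must be a single (optionally tagged) reaction")
    output = _resolve_atom(tokens[0], net)
    parser = _Parser(tokens[eq + 1 :], net)
    expr = parser.parse_expr()
    if parser.peek() is not None:
        raise RuleError(f"trailing tokens after expression: {parser.peek()!r}")
    return Rule(output=output, expr=expr, source_text=text.strip(), rule_id=rule_id)


def parse_rules(path: str | Path, net: MetabolicNetwork) -> list[Rule]:
    """Parse a rule file: one rule per line, ``#`` comments, ids ``GR1``… in
    file order."""
    rules: list[Rule] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rules.append(parse_rule_line(line, net, rule_id=f"GR{len(rules) + 1}"))
        except RuleError as exc:
            raise RuleError(f"{path}:{lineno}: {exc}") from None
    if not rules:
        log.warning("rule file %s contains no rules", path)
    return rules


# ---------------------------------------------------------------------------
# Evaluation

def eval_tribool(expr: Expr, assignment: Mapping[str, int]) -> TriBool:
    """Evaluate an expression under Kleene's strong three-valued semantics.

    ``assignment`` maps reaction id to its flux bit (0/1).
    """
    if isinstance(expr, RuleAtom):
        return expr.value(assignment[expr.reaction])
    if isinstance(expr, Not):
        v = eval_tribool(expr.operand, assignment)
        return None if v is None else not v
    a = eval_tribool(expr.left, assignment)
    b = eval_tribool(expr.right, assignment)
    if isinstance(expr, And):
        if a is False or b is False:
            return False
        if a is None or b is None:
            return None
        return True
    if a is True or b is True:
        return True
    if a is None or b is None:
        return None
    return False


def rule_violated(rule: Rule, assignment: Mapping[str, int]) -> bool:
    """True iff output and expression are both defined and disagree."""
    lhs = rule.output.value(assignment[rule.output.reaction])
    if lhs is None:
        return False
    rhs = eval_tribool(rule.expr, assignment)
    if rhs is None:
        return False
    return lhs != rhs


def classify_rule(rule: Rule) -> RuleClass:
    """Iteration-phase eligibility test.

    A rule may prune during the iteration iff, with every input reaction
    carrying flux, the expression is definitely false while the output
    occurrence is defined at flux 1 — i.e. a flux-carrying mode activating
    all participants provably violates the rule, and so does every child by
    OR-monotonicity.
    """
    all_on = {rid: 1 for rid in rule.involved_reactions()}
    if eval_tribool(rule.expr, all_on) is not False:
        return RuleClass.POST_ONLY
    if rule.output.value(1) is None:
        return RuleClass.POST_ONLY
    return RuleClass.ITERATION_PHASE


def compile_patterns(rules: Sequence[Rule], ext: ExtendedNetwork) -> list[RulePattern]:
    """Compile iteration-phase rules to bit patterns over extended columns.

    Each pattern sets one extended column per involved reaction; reversible
    participants contribute a forward and a backward alternative, so a rule
    with *k* reversible participants yields ``2**k`` patterns (a reversible
    reaction carries flux iff its forward OR backward column does).
    """
    from itertools import product

    patterns: list[RulePattern] = []
    for rule in rules:
        if classify_rule(rule) is not RuleClass.ITERATION_PHASE:
            continue
        alternatives = [ext.col_map[rid] for rid in rule.involved_reactions()]
        for choice in product(*alternatives):
            bits = 0
            for col in choice:
                bits |= 1 << col
            patterns.append(RulePattern(bits=bits, rule_id=rule.rule_id))
    return patterns
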