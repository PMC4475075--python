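"""Shared fixtures: the worked example, frozen published values, and helpers."""

from __future__ import annotations

from fractions import Fraction

import pytest

from regefm.kernel_init import KernelMatrix
from regefm.network_io import (
    MetabolicNetwork,
    ReactionSpec,
    split_reversibles,
)
from regefm.oracle_fixtures import fig1_kernel, fig1_network, fig1_rules

# Published numeric EFMs of the worked example (reaction order R1..R11,
# max-abs normalized, reversible R7r signed as forward - backward).
EFMS_UNREGULATED = [
    "0.00 1.00 0.00 0.50 0.00 0.00 -0.50 0.50 0.00 0.00 0.00",
    "0.00 1.00 0.00 0.25 0.50 0.00 -0.50 0.00 0.25 0.00 0.50",
    "0.00 1.00 0.00 0.25 0.00 0.50 -1.00 0.00 0.25 0.50 0.00",
    "0.00 0.00 1.00 0.50 0.00 1.00 -1.00 0.00 0.50 1.00 0.00",
    "0.50 1.00 0.00 1.00 0.00 0.00 0.00 1.00 0.00 0.00 0.00",
    "0.50 1.00 0.00 0.50 1.00 0.00 0.00 0.00 0.50 0.00 1.00",
    "1.00 0.00 0.00 0.50 0.00 1.00 0.00 0.00 0.50 1.00 0.00",
    "1.00 0.00 0.00 0.50 1.00 0.00 1.00 0.00 0.50 0.00 1.00",
    "1.00 0.00 0.00 1.00 0.00 0.00 1.00 1.00 0.00 0.00 0.00",
    "0.00 0.00 1.00 0.50 1.00 0.00 0.00 0.00 0.50 0.00 1.00",
    "0.00 0.00 1.00 1.00 0.00 0.00 0.00 1.00 0.00 0.00 0.00",
]
EFMS_REGULATED_FULL = [
    "0.50 1.00 0.00 0.50 1.00 0.00 0.00 0.00 0.50 0.00 1.00",
    "0.00 1.00 0.00 0.50 0.00 0.00 -0.50 0.50 0.00 0.00 0.00",
    "1.00 0.00 0.00 0.50 0.00 1.00 0.00 0.00 0.50 1.00 0.00",
    "1.00 0.00 0.00 1.00 0.00 0.00 1.00 1.00 0.00 0.00 0.00",
    "0.00 0.00 1.00 0.50 1.00 0.00 0.00 0.00 0.50 0.00 1.00",
]

# Published iteration-order of the worked example's kernel rows and the
# numeric-tail multiset after the first iteration step.
TABLE2_ORDER = ["R3", "R4", "R5", "R6", "R7f", "R7b", "R8", "R9", "R10", "R11", "R2", "R1"]
FIRST_STEP_TAILS = ["-0.5", "0.5", "1.0", "0.5", "0.5", "0.5", "0.0", "0.0", "0.0", "-0.5"]


def parse_flux_row(text: str) -> tuple[Fraction, ...]:
    return tuple(Fraction(x) for x in text.split())


def efm_set(rows: list[str]) -> set[tuple[Fraction, ...]]:
    return {parse_flux_row(r) for r in rows}


@pytest.fixture(scope="session")
def fig1_net():
    return fig1_network()


@pytest.fixture(scope="session")
def fig1_ext(fig1_net):
    return split_reversibles(fig1_net)


@pytest.fixture(scope="session")
def fig1_km(fig1_ext):
    return fig1_kernel(fig1_ext)


@pytest.fixture(scope="session")
def fig1_rule_variants(fig1_net):
    return {v: fig1_rules(v, fig1_net) for v in ("none", "one_active", "full_active")}


def tiny_network(n_reactions=3, reversible=()):
    """A linear chain uptake -> A -> ... -> secretion, for edge-case tests."""
    n_met = n_reactions - 1
    reactions = [
        ReactionSpec(id=f"R{j + 1}", reversible=(j + 1) in reversible)
        for j in range(n_reactions)
    ]
    S = []
    for i in range(n_met):
        row = [Fraction(0)] * n_reactions
        row[i] = Fraction(1)
        row[i + 1] = Fraction(-1)
        S.append(row)
    return MetabolicNetwork(
        metabolite_ids=[f"M{i + 1}" for i in range(n_met)], reactions=reactions, S=S
    )


def reorder_example_kernel():
    """Synthetic 17-row kernel reproducing the published reordering example.

    Reaction names, reversibility pattern, and per-row adjacency-candidate
    counts match the published table; the kernel entries themselves are
    synthetic (the example's stoichiometry is not available), which is all
    the ordering operation looks at.
    """
    F = Fraction
    reversible = {"R4", "R6", "R7", "R11", "R12"}
    reactions = [
        ReactionSpec(id=f"R{j + 1}", reversible=f"R{j + 1}" in reversible)
        for j in range(12)
    ]
    S = [[F(1)] * 12]  # dummy single-metabolite stoichiometry; never solved
    net = MetabolicNetwork(metabolite_ids=["M1"], reactions=reactions, S=S)
    ext = split_reversibles(net)
    rows = {
        # tail rows with the published (negative x positive) candidate counts
        "R11f": [-1, 1, 1, 0, 0, 0, 0],   # 1x2 = 2
        "R5":   [-1, -1, 1, 1, 0, 0, 0],  # 2x2 = 4
        "R1":   [-1, -1, 1, 1, 1, 0, 0],  # 2x3 = 6
        "R2":   [-1, 1, -1, 1, 0, 1, 0],  # 2x3 = 6
        "R4f":  [-1, -1, -1, 1, 1, 1, 1], # 3x4 = 12
    }
    K = []
    for rid in ext.ext_reaction_ids:
        K.append([F(x) for x in rows.get(rid, [1, 0, 1, 0, 1, 0, 1])])
    order = list(range(ext.n_ext))
    return KernelMatrix(K=K, ext=ext, row_order=order, n_binarizable=0), net
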