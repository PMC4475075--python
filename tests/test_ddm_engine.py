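"""The binary double-description iteration and its pruning semantics."""

import random
from fractions import Fraction
from itertools import combinations

import pytest

from regefm.ddm_engine import (
    Mode,
    ModeMatrix,
    adjacency_test,
    combine,
    iterate_row,
    run,
)
from regefm.kernel_init import compute_kernel, init_mode_matrix, order_rows
from regefm.network_io import split_reversibles
from regefm.oracle_fixtures import GeneratorConfig, generate_network
from regefm.postprocess import merge_all, remove_futile_cycles
from regefm.rule_engine import compile_patterns, parse_rule_line

from conftest import FIRST_STEP_TAILS

F = Fraction


@pytest.fixture
def fig1_R0(fig1_km):
    return init_mode_matrix(order_rows(fig1_km))


def _mode_names(matrix, ext, mode):
    return {
        ext.ext_reaction_ids[matrix.binarized_rows[p]]
        for p in range(len(matrix.binarized_rows))
        if mode.support >> p & 1
    }


def test_combine_published_first_step(fig1_R0, fig1_ext):
    m1, m2, m3 = fig1_R0.modes[0], fig1_R0.modes[1], fig1_R0.modes[2]
    child = combine(m_pos=m3, m_neg=m1)  # pivot row R2: -1 vs +1
    assert _mode_names(fig1_R0, fig1_ext, child) == {"R3", "R7b"}
    assert child.tail == (F(0), F("-0.5"))

    child2 = combine(m_pos=m3, m_neg=m2)
    assert _mode_names(fig1_R0, fig1_ext, child2) == {"R7f", "R7b"}
    assert child2.tail == (F(0), F(0))


def test_combine_pivot_cancels_exactly():
    a = Mode(support=0b01, tail=(F(3, 7), F(1)))
    b = Mode(support=0b10, tail=(F(-2, 5), F(1, 3)))
    child = combine(a, b)
    assert child.tail[0] == 0
    assert child.support == 0b11


def test_combine_sign_precondition():
    a = Mode(support=0, tail=(F(1),))
    with pytest.raises(ValueError):
        combine(a, a)


def test_adjacency_rejects_equal_third_mode():
    p0 = Mode(support=0b0011, tail=())
    p1 = Mode(support=0b0101, tail=())
    third = Mode(support=0b0111, tail=())
    assert adjacency_test(p0.support | p1.support, [p0, p1, third], (p0, p1)) is False
    assert adjacency_test(p0.support | p1.support, [p0, p1], (p0, p1)) is True


@pytest.mark.parametrize("seed", [5, 6, 7])
def test_adjacency_agrees_with_subset_oracle(seed):
    rng = random.Random(seed)
    modes = [Mode(support=rng.getrandbits(12) | 1, tail=()) for _ in range(12)]
    for a, b in combinations(range(len(modes)), 2):
        cand = modes[a].support | modes[b].support
        expected = not any(
            modes[c].support | cand == cand
            for c in range(len(modes))
            if c not in (a, b)
        )
        assert adjacency_test(cand, modes, (modes[a], modes[b])) is expected


def test_first_iteration_unregulated(fig1_R0):
    out, stats = iterate_row(fig1_R0)
    assert len(out.modes) == 10
    tails = sorted(m.tail[0] for m in out.modes)
    assert tails == sorted(F(t) for t in FIRST_STEP_TAILS)
    assert stats.n_adjacency_candidates == 6  # 2 negative x 3 positive
    assert stats.removed_infeasible == 0


def test_first_iteration_with_pattern(fig1_R0, fig1_net, fig1_ext):
    patterns = compile_patterns([parse_rule_line("R7r = NOT(fR9)", fig1_net)], fig1_ext)
    out, stats = iterate_row(fig1_R0, patterns)
    assert len(out.modes) == 9
    assert stats.removed_infeasible == 1
    for m in out.modes:  # no surviving mode activates R7f/R7b together with R9
        names = _mode_names(out, fig1_ext, m)
        assert not ({"R7f", "R9"} <= names or {"R7b", "R9"} <= names)


def test_pivot_row_without_negatives_only_binarizes():
    matrix = ModeMatrix(
        modes=[Mode(0b1, (F(2), F(-1))), Mode(0b0, (F(0), F(1)))],
        binarized_rows=[0],
        pending_rows=[1, 2],
    )
    out, stats = iterate_row(matrix)
    assert len(out.modes) == 2
    assert stats.n_adjacency_candidates == 0
    assert out.modes[0].support == 0b11  # positive pivot sets the new bit


def test_run_unregulated_final_count(fig1_R0):
    final, stats = run(fig1_R0)
    assert final.fully_binary
    assert len(final.modes) == 12
    assert [s.n_modes for s in stats] == [10, 12]


def test_run_regulated_final_count(fig1_R0, fig1_net, fig1_ext):
    patterns = compile_patterns([parse_rule_line("R7r = NOT(fR9)", fig1_net)], fig1_ext)
    final, stats = run(fig1_R0, patterns)
    assert len(final.modes) == 8
    assert [s.removed_infeasible for s in stats] == [1, 3]


def test_run_with_no_pending_rows_is_identity():
    matrix = ModeMatrix(modes=[Mode(0b1, ())], binarized_rows=[0], pending_rows=[])
    out, stats = run(matrix)
    assert out.modes == matrix.modes
    assert stats == []


def _final_supports(net, patterns=()):
    ext = split_reversibles(net)
    R0 = init_mode_matrix(order_rows(compute_kernel(ext)))
    final, _ = run(R0, patterns)
    final = remove_futile_cycles(final, ext)
    return {e.support for e in merge_all(final, ext)}


@pytest.mark.parametrize("seed", [41, 42, 43, 44])
def test_rule_equivalence_pruning_loses_nothing(seed):
    """Running with patterns equals running unconstrained and filtering
    pattern-containing supports afterwards (the pruning is exact)."""
    net = generate_network(GeneratorConfig(n_metabolites=4, n_reactions=9,
                                           reversible_fraction=0.25, seed=seed))
    ext = split_reversibles(net)
    rule = parse_rule_line("R2 = NOT(fR5)", net)
    patterns = compile_patterns([rule], ext)
    assert patterns

    pruned = _final_supports(net, patterns)

    R0 = init_mode_matrix(order_rows(compute_kernel(ext)))
    final, _ = run(R0)
    final = remove_futile_cycles(final, ext)
    filtered = set()
    for mode, efm in zip(final.modes, merge_all(final, ext)):
        ext_support = 0
        for p in range(len(final.binarized_rows)):
            if mode.support >> p & 1:
                ext_support |= 1 << final.binarized_rows[p]
        if not any(ext_support & pat.bits == pat.bits for pat in patterns):
            filtered.add(efm.support)
    assert pruned == filtered


@pytest.mark.parametrize("seed", [51, 52])
def test_final_support_set_is_order_invariant(seed):
    """Admissible row reorderings (non-negative block first, otherwise
    arbitrary) never change the final EFM support set."""
    net = generate_network(GeneratorConfig(n_metabolites=4, n_reactions=9,
                                           reversible_fraction=0.25, seed=seed))
    ext = split_reversibles(net)
    km = order_rows(compute_kernel(ext))
    reference = _final_supports(net)
    rng = random.Random(seed)
    for _ in range(3):
        nonneg = [i for i in km.row_order if not any(x < 0 for x in km.K[i])]
        tail = [i for i in km.row_order if any(x < 0 for x in km.K[i])]
        rng.shuffle(nonneg)
        rng.shuffle(tail)
        from dataclasses import replace

        shuffled = replace(km, row_order=nonneg + tail, n_binarizable=len(nonneg))
        final, _ = run(init_mode_matrix(shuffled))
        final = remove_futile_cycles(final, ext)
        assert {e.support for e in merge_all(final, ext)} == reference
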