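"""Binary double-description iteration with rule-pattern pruning.

Each intermediate mode is a hybrid of a binary support (one bit per already
processed reaction row; 1 = carries flux) and a rational tail over the rows
still numeric.  One iteration converts the first pending row: modes with a
non-negative pivot entry survive (positive → bit 1, zero → bit 0), each
negative×positive pair passing the combinatorial adjacency test produces a
child whose support is the bitwise OR of its parents and whose tail is the
weighted combination

    v_new_r = (v1+ · vr−  −  v1− · vr+) / (v1+ − v1−),

which cancels the pivot entry exactly.  Because the OR never clears a bit,
any mode whose support contains all bits of a compiled rule pattern can only
breed rule-violating descendants, so such modes are deleted after every step
without losing feasible elementary flux modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .rule_engine import RulePattern


@dataclass(frozen=True)
class Mode:
    """Intermediate mode: binary support + numeric tail.

    ``support`` is a bit mask indexed by position in the owning matrix's
    ``binarized_rows``; ``tail`` is aligned with ``pending_rows``.
    """

    support: int
    tail: tuple[Fraction, ...]


@dataclass
class ModeMatrix:
    """The mode matrix R: all modes share one binarized/pending row split."""

    modes: list[Mode]
    binarized_rows: list[int]
    pending_rows: list[int]

    @property
    def fully_binary(self) -> bool:
        return not self.pending_rows


@dataclass(frozen=True)
class IterationStats:
    """Per-iteration trace: pattern removals, surviving mode count, and the
    negative×positive candidate-pair count of the step."""

    iteration_no: int
    removed_infeasible: int
    n_modes: int
    n_adjacency_candidates: int


def combine(m_pos: Mode, m_neg: Mode, pivot: int = 0) -> Mode:
    """Combine a positive and a negative parent at a pivot tail row.

    The child support is the bitwise OR of the parents'; every tail entry is
    the weighted subtraction above, which is exactly zero at the pivot.
    """
    v1p = m_pos.tail[pivot]
    v1n = m_neg.tail[pivot]
    if not (v1p > 0 and v1n < 0):
        raise ValueError("combine() needs a positive and a negative pivot entry")
    denom = v1p - v1n
    tail = tuple(
        (v1p * vn - v1n * vp) / denom for vp, vn in zip(m_pos.tail, m_neg.tail)
    )
    assert tail[pivot] == 0
    return Mode(support=m_pos.support | m_neg.support, tail=tail)


def adjacency_test(
    candidate_support: int, keep: Sequence[Mode], parents: tuple[Mode, Mode]
) -> bool:
    """Combinatorial adjacency: keep a candidate child only if no existing
    mode other than its parents has a support contained in (or equal to) the
    candidate's support."""
    p0, p1 = parents
    for mode in keep:
        if mode is p0 or mode is p1:
            continue
        if mode.support | candidate_support == candidate_support:
            return False
    return True


def _applicable_masks(
    patterns: Sequence[RulePattern], binarized_rows: Sequence[int]
) -> list[int]:
    """Translate patterns to support-position masks; a pattern applies only
    once every reaction it involves has been binarized."""
    position = {ext: pos for pos, ext in enumerate(binarized_rows)}
    masks = []
    for pat in patterns:
        cols = pat.ext_indices()
        if all(c in position for c in cols):
            mask = 0
            for c in cols:
                mask |= 1 << position[c]
            masks.append(mask)
    return masks


def prune_infeasible(
    matrix: ModeMatrix, patterns: Sequence[RulePattern]
) -> tuple[ModeMatrix, int]:
    """Drop modes whose support contains any applicable rule pattern."""
    masks = _applicable_masks(patterns, matrix.binarized_rows)
    if not masks:
        return matrix, 0
    kept = [
        m for m in matrix.modes
        if not any(m.support & mask == mask for mask in masks)
    ]
    removed = len(matrix.modes) - len(kept)
    return (
        ModeMatrix(kept, list(matrix.binarized_rows), list(matrix.pending_rows)),
        removed,
    )


def iterate_row(
    matrix: ModeMatrix,
    patterns: Sequence[RulePattern] = (),
    iteration_no: int = 1,
) -> tuple[ModeMatrix, IterationStats]:
    """Convert the first pending row to binary form.

    Children are appended after the kept modes in deterministic
    (negative-parent index, positive-parent index) order; rule patterns are
    applied after the full step, children included.
    """
    if not matrix.pending_rows:
        raise ValueError("no pending rows left to iterate")
    pos = [m for m in matrix.modes if m.tail[0] > 0]
    neg = [m for m in matrix.modes if m.tail[0] < 0]

    def shift(mode: Mode, bit: int) -> Mode:
        support = mode.support | bit << len(matrix.binarized_rows)
        return Mode(support=support, tail=mode.tail[1:])

    new_modes = [shift(m, int(m.tail[0] > 0)) for m in matrix.modes if m.tail[0] >= 0]
    for m_neg in neg:
        for m_pos in pos:
            cand = m_pos.support | m_neg.support
            if adjacency_test(cand, matrix.modes, (m_pos, m_neg)):
                new_modes.append(shift(combine(m_pos, m_neg), 0))

    out = ModeMatrix(
        modes=new_modes,
        binarized_rows=matrix.binarized_rows + [matrix.pending_rows[0]],
        pending_rows=matrix.pending_rows[1:],
    )
    out, removed = prune_infeasible(out, patterns)
    stats = IterationStats(
        iteration_no=iteration_no,
        removed_infeasible=removed,
        n_modes=len(out.modes),
        n_adjacency_candidates=len(neg) * len(pos),
    )
    return out, stats


def run(
    matrix: ModeMatrix, patterns: Sequence[RulePattern] = ()
) -> tuple[ModeMatrix, list[IterationStats]]:
    """Iterate until every mode is fully binary.

    The pattern check also runs once on the initial matrix (recorded as
    iteration 0 when it removes anything), since an initial basis mode may
    already activate every reaction of a pattern.
    """
    stats: list[IterationStats] = []
    matrix, removed = prune_infeasible(matrix, patterns)
    if removed:
        stats.append(IterationStats(0, removed, len(matrix.modes), 0))
    it = 0
    while matrix.pending_rows:
        it += 1
        matrix, st = iterate_row(matrix, patterns, iteration_no=it)
        stats.append(st)
    return matrix, stats
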