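"""From the final binary mode matrix to the feasible numeric EFM set.

Order of operations after the iteration terminates: drop the futile 2-cycle
artifacts created by splitting reversible reactions, merge each
forward/backward pair back into its reversible reaction by bitwise OR,
re-check every regulatory rule on the merged binary supports (the
post-processing check reaches the rule branches the iteration-phase patterns
cannot see, e.g. conditions on inactive reactions), and finally recover
exact numeric flux vectors from the kernel.

Numeric recovery uses the reduced null-space idea: restricting the kernel to
the rows of reactions *inactive* in a mode leaves a coefficient space whose
image in flux space is one-dimensional for a genuine elementary mode.  To
keep the system one-dimensional in the presence of split reversibles, the
kernel rows of a forward/backward pair are first merged as forward −
backward (the futile 2-cycle direction is annihilated by that merge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from ._linalg import Matrix, mat_vec, nullspace, rank
from .ddm_engine import Mode, ModeMatrix
from .kernel_init import KernelMatrix
from .network_io import ExtendedNetwork, MetabolicNetwork
from .rule_engine import Rule, rule_violated

log = logging.getLogger(__name__)


class ElementarityError(ValueError):
    """A support whose restricted null space is not one-dimensional."""


@dataclass(frozen=True)
class BinaryEFM:
    """Support bit mask over the *original* (merged) reaction order."""

    support: int

    def active(self, net: MetabolicNetwork) -> list[str]:
        return [r.id for j, r in enumerate(net.reactions) if self.support >> j & 1]

    def assignment(self, net: MetabolicNetwork) -> dict[str, int]:
        return {r.id: self.support >> j & 1 for j, r in enumerate(net.reactions)}


@dataclass(frozen=True)
class NumericEFM:
    """Exact flux vector over the original reaction order.

    Irreversible entries are non-negative; reversible entries carry the net
    forward − backward flux and may have either sign.
    """

    flux: tuple[Fraction, ...]

    def support_mask(self) -> int:
        mask = 0
        for j, x in enumerate(self.flux):
            if x != 0:
                mask |= 1 << j
        return mask


def _support_positions(mode: Mode, matrix: ModeMatrix) -> set[int]:
    return {
        matrix.binarized_rows[pos]
        for pos in range(len(matrix.binarized_rows))
        if mode.support >> pos & 1
    }


def remove_futile_cycles(matrix: ModeMatrix, ext: ExtendedNetwork) -> ModeMatrix:
    """Remove every mode whose support is exactly one reversible reaction's
    forward+backward pair — an artifact of the splitting step."""
    if not matrix.fully_binary:
        raise ValueError("futile-cycle removal needs a fully binary matrix")
    pairs = {frozenset(cols) for cols in ext.col_map.values() if len(cols) == 2}
    kept = [
        m for m in matrix.modes
        if frozenset(_support_positions(m, matrix)) not in pairs
    ]
    return ModeMatrix(kept, list(matrix.binarized_rows), [])


def merge_reversibles(mode: Mode, matrix: ModeMatrix, ext: ExtendedNetwork) -> BinaryEFM:
    """Collapse forward/backward bits onto the original reaction by OR."""
    active_ext = _support_positions(mode, matrix)
    mask = 0
    for j, rid in enumerate(ext.base.reaction_ids):
        if any(c in active_ext for c in ext.col_map[rid]):
            mask |= 1 << j
    return BinaryEFM(support=mask)


def merge_all(matrix: ModeMatrix, ext: ExtendedNetwork) -> list[BinaryEFM]:
    return [merge_reversibles(m, matrix, ext) for m in matrix.modes]


def apply_post_rules(
    efms: Sequence[BinaryEFM], rules: Sequence[Rule], net: MetabolicNetwork
) -> list[BinaryEFM]:
    """Keep only EFMs obeying every rule under three-valued evaluation."""
    if not rules:
        return list(efms)
    kept = []
    for efm in efms:
        assignment = efm.assignment(net)
        if not any(rule_violated(rule, assignment) for rule in rules):
            kept.append(efm)
    if len(kept) != len(efms):
        log.info("post-processing rules removed %d modes", len(efms) - len(kept))
    return kept


def _merged_kernel_rows(K: Matrix, ext: ExtendedNetwork) -> Matrix:
    rows = []
    for rid in ext.base.reaction_ids:
        cols = ext.col_map[rid]
        if len(cols) == 2:
            rows.append([a - b for a, b in zip(K[cols[0]], K[cols[1]])])
        else:
            rows.append(list(K[cols[0]]))
    return rows


def recover_numeric(efm: BinaryEFM, km: KernelMatrix, ext: ExtendedNetwork) -> NumericEFM:
    """Solve the reduced homogeneous system for a mode's exact fluxes.

    The coefficient space of the kernel restricted to inactive merged rows
    may have extra dimensions that map to zero flux (split reversibles); the
    image in flux space must be exactly one-dimensional.  The sign is chosen
    so every irreversible entry is non-negative.
    """
    merged = _merged_kernel_rows(km.K, ext)
    net = ext.base
    inactive = [j for j in range(len(net.reactions)) if not efm.support >> j & 1]
    Z = [merged[j] for j in inactive]
    coeffs = nullspace(Z, n_cols=km.n_modes)
    fluxes = [mat_vec(merged, c) for c in coeffs]
    nonzero = [v for v in fluxes if any(x != 0 for x in v)]
    if not nonzero or rank(nonzero) != 1:
        raise ElementarityError(
            f"support {efm.active(net)} does not determine a unique flux direction"
        )
    v = nonzero[0]
    for j, rxn in enumerate(net.reactions):
        if not rxn.reversible and v[j] != 0:
            if v[j] < 0:
                v = [-x for x in v]
            break
    else:
        first = next(x for x in v if x != 0)
        if first < 0:
            v = [-x for x in v]
    if any(v[j] < 0 for j, r in enumerate(net.reactions) if not r.reversible):
        raise ElementarityError("recovered flux violates irreversibility")
    if NumericEFM(tuple(v)).support_mask() != efm.support:
        raise ElementarityError("recovered flux support differs from binary support")
    return NumericEFM(flux=tuple(v))


def recover_numeric_from_S(efm: BinaryEFM, net: MetabolicNetwork) -> NumericEFM:
    """Independent recovery route: null space of S restricted to the active
    columns (used as a cross-check when S is available)."""
    active = [j for j in range(len(net.reactions)) if efm.support >> j & 1]
    sub = [[row[j] for j in active] for row in net.S]
    basis = nullspace(sub, n_cols=len(active))
    if len(basis) != 1:
        raise ElementarityError(
            f"support {efm.active(net)} has a {len(basis)}-dimensional null space"
        )
    v = [Fraction(0)] * len(net.reactions)
    for j, x in zip(active, basis[0]):
        v[j] = x
    for j in active:
        if not net.reactions[j].reversible and v[j] != 0:
            if v[j] < 0:
                v = [-x for x in v]
            break
    else:
        if v[active[0]] < 0:
            v = [-x for x in v]
    if any(x == 0 for x in (v[j] for j in active)):
        raise ElementarityError("restricted null vector vanishes on the support")
    if any(v[j] < 0 for j, r in enumerate(net.reactions) if not r.reversible):
        raise ElementarityError("recovered flux violates irreversibility")
    return NumericEFM(flux=tuple(v))


def normalize(flux: Sequence[Fraction]) -> tuple[Fraction, ...]:
    """Scale so the maximum absolute entry is exactly 1."""
    m = max(abs(x) for x in flux)
    if m == 0:
        raise ValueError("cannot normalize the zero vector")
    return tuple(x / m for x in flux)


def activity_frequencies(
    efms: Sequence[BinaryEFM], net: MetabolicNetwork
) -> dict[str, Fraction]:
    """Per-reaction activity frequency α_i: the percentage of EFMs in which
    reaction i carries flux."""
    if not efms:
        raise ValueError("activity frequencies need a non-empty EFM set")
    n = len(efms)
    out: dict[str, Fraction] = {}
    for j, rxn in enumerate(net.reactions):
        count = sum(1 for e in efms if e.support >> j & 1)
        out[rxn.id] = Fraction(100 * count, n)
    return out


def activity_comparison(
    efms_without: Sequence[BinaryEFM],
    efms_with: Sequence[BinaryEFM],
    net: MetabolicNetwork,
) -> list[tuple[str, Fraction, Fraction, Fraction]]:
    """Per-reaction α without/with regulation and the α_w − α_w/o change.

    The interesting rows are reactions whose activity frequency shifts a
    lot even though no rule mentions them — system-wide effects of the
    network structure under regulation.
    """
    a = activity_frequencies(efms_without, net)
    b = activity_frequencies(efms_with, net)
    return [(rid, a[rid], b[rid], b[rid] - a[rid]) for rid in a]
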