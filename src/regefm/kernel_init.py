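"""Initial kernel of the extended stoichiometric matrix and its row ordering.

The double-description iteration starts from a rational basis ``K`` of the
right null space of ``S_ext`` (one row per extended reaction, one column per
basis vector).  Rows free of negative entries describe reactions whose flux
sign is already decided in every basis mode, so they can be binarized before
the iteration even starts; ordering puts them first.  The remaining rows are
sorted by increasing potential adjacency candidates — (#negative entries) ×
(#positive entries) — since cheap rows spawn fewer candidate pairs.  With
rule-aware sorting, rows of reactions participating in regulatory rules move
directly behind the non-negative block so their bits become available to the
pruning patterns as early as possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from ._linalg import Matrix, format_rational, mat_vec, nullspace, parse_rational
from .ddm_engine import Mode, ModeMatrix
from .network_io import ExtendedNetwork, NetworkFormatError
from .rule_engine import Rule

log = logging.getLogger(__name__)


class KernelValidationError(ValueError):
    """Raised when a supplied kernel is not a null-space basis of S_ext."""


@dataclass
class KernelMatrix:
    """Null-space basis with an iteration row order.

    ``K`` keeps rows in the extended-column order of ``ext``; ``row_order``
    is the permutation applied for the iteration phase.  The first
    ``n_binarizable`` rows of the ordered matrix contain no negative entry.
    """

    K: Matrix
    ext: ExtendedNetwork
    row_order: list[int]
    n_binarizable: int

    @property
    def n_modes(self) -> int:
        return len(self.K[0]) if self.K else 0

    def ordered_rows(self) -> Matrix:
        return [self.K[i] for i in self.row_order]

    def ordered_ids(self) -> list[str]:
        return [self.ext.ext_reaction_ids[i] for i in self.row_order]


def _leading_nonnegative(K: Matrix, order: Sequence[int]) -> int:
    n = 0
    for i in order:
        if any(x < 0 for x in K[i]):
            break
        n += 1
    return n


def compute_kernel(ext: ExtendedNetwork) -> KernelMatrix:
    """Exact rational right null-space basis of ``S_ext``.

    Deterministic for a fixed input (fixed Gauss–Jordan pivot rule).  A
    0-dimensional null space means no steady-state flux is possible; the
    result is then empty and a warning is logged.
    """
    basis = nullspace(ext.S_ext, n_cols=ext.n_ext)
    if not basis:
        log.warning("null space of S_ext is 0-dimensional: no flux possible")
        K: Matrix = [[] for _ in range(ext.n_ext)]
    else:
        K = [[vec[i] for vec in basis] for i in range(ext.n_ext)]
    order = list(range(ext.n_ext))
    return KernelMatrix(K=K, ext=ext, row_order=order,
                        n_binarizable=_leading_nonnegative(K, order))


def load_kernel(path: str | Path, ext: ExtendedNetwork, validate: bool = True) -> KernelMatrix:
    """Load a kernel TSV (reaction id column + rational basis entries).

    Row labels must cover the extended reaction ids exactly; when
    ``validate`` the product ``S_ext · K = 0`` is checked entry-wise.
    Loading exists because a null-space basis is not unique: it lets a
    published kernel be reproduced verbatim.
    """
    rows: dict[str, list[Fraction]] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        rid = parts[0].strip()
        if rid in rows:
            raise NetworkFormatError(f"{path}:{lineno}: duplicate kernel row {rid!r}")
        try:
            rows[rid] = [parse_rational(x) for x in parts[1:]]
        except ValueError as exc:
            raise NetworkFormatError(f"{path}:{lineno}: {exc}")
    unknown = set(rows) - set(ext.ext_reaction_ids)
    missing = set(ext.ext_reaction_ids) - set(rows)
    if unknown or missing:
        raise NetworkFormatError(
            f"{path}: kernel rows do not match extended reactions "
            f"(unknown={sorted(unknown)}, missing={sorted(missing)})"
        )
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise NetworkFormatError(f"{path}: ragged kernel rows")
    K = [rows[rid] for rid in ext.ext_reaction_ids]
    if validate:
        n_basis = widths.pop()
        for j in range(n_basis):
            col = [K[i][j] for i in range(ext.n_ext)]
            if any(x != 0 for x in mat_vec(ext.S_ext, col)):
                raise KernelValidationError(
                    f"{path}: kernel column {j + 1} is not in the null space of S_ext"
                )
    else:
        log.warning("kernel %s accepted without S_ext validation", path)
    order = list(range(ext.n_ext))
    return KernelMatrix(K=K, ext=ext, row_order=order,
                        n_binarizable=_leading_nonnegative(K, order))


def write_kernel(km: KernelMatrix, path: str | Path) -> None:
    lines = []
    for i, rid in enumerate(km.ext.ext_reaction_ids):
        lines.append(rid + "\t" + "\t".join(format_rational(x) for x in km.K[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def count_adjacency_candidates(row: Sequence[Fraction]) -> int:
    """Potential adjacency candidates of a kernel row:
    (#negative entries) × (#positive entries)."""
    neg = sum(1 for x in row if x < 0)
    pos = sum(1 for x in row if x > 0)
    return neg * pos


def order_rows(km: KernelMatrix, rules: Sequence[Rule] = (), rule_sort: bool = False) -> KernelMatrix:
    """Order kernel rows for the iteration phase.

    1. rows without negative entries first (original relative order kept);
    2. remaining rows by increasing adjacency-candidate count, ties broken
       by original extended-column index (stable);
    3. with ``rule_sort``, rows of reactions participating in any given rule
       move directly behind the non-negative block, keeping their
       candidate-sorted relative order.  Rows already inside the
       non-negative block never move.
    """
    nonneg = [i for i in km.row_order if not any(x < 0 for x in km.K[i])]
    tail = [i for i in km.row_order if any(x < 0 for x in km.K[i])]
    tail.sort(key=lambda i: (count_adjacency_candidates(km.K[i]), i))
    if rule_sort and rules:
        ruled_cols: set[int] = set()
        for rule in rules:
            for rid in rule.involved_reactions():
                ruled_cols.update(km.ext.col_map[rid])
        tail = [i for i in tail if i in ruled_cols] + [i for i in tail if i not in ruled_cols]
    order = nonneg + tail
    return replace(km, row_order=order, n_binarizable=_leading_nonnegative(km.K, order))


def init_mode_matrix(km: KernelMatrix) -> ModeMatrix:
    """One mode per kernel column: a binary prefix over the first
    ``n_binarizable`` ordered rows (bit set iff the entry is nonzero) and an
    exact rational tail over the rest."""
    nb = km.n_binarizable
    binarized = km.row_order[:nb]
    pending = km.row_order[nb:]
    modes = []
    for j in range(km.n_modes):
        support = 0
        for pos, i in enumerate(binarized):
            if km.K[i][j] != 0:
                support |= 1 << pos
        tail = tuple(km.K[i][j] for i in pending)
        modes.append(Mode(support=support, tail=tail))
    return ModeMatrix(modes=modes, binarized_rows=list(binarized), pending_rows=list(pending))
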