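"""Independent brute-force EFM enumeration, worked-example fixtures, and a
seeded random-network generator.

The brute-force enumerator is deliberately not a double-description variant:
it tests every candidate support of the extended network directly against
the defining property of an elementary flux mode — the null space of
``S_ext`` restricted to the support columns is exactly one-dimensional with
a strictly positive representative.  That makes it a maximally independent
oracle for the iteration engine, at the price of exponential cost, so it
refuses networks with more than 16 extended reactions.

The bundled worked example is a 12-metabolite, 11-reaction network with one
reversible reaction (R7r) and the published 6-column kernel of its extended
form.  The stoichiometric rows are a *synthetic reconstruction*: integer
vectors spanning the left null space of the published kernel (6 independent
rows plus 6 dependent combinations standing in for redundant conservation
relations).  Any matrix with that row space has the same flux cone, hence
exactly the published EFM set; the tests re-verify this.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from itertools import combinations
from pathlib import Path

from ._linalg import nullspace, rank
from .kernel_init import KernelMatrix, load_kernel
from .network_io import (
    ExtendedNetwork,
    MetabolicNetwork,
    ReactionSpec,
    read_network_tsv,
    split_reversibles,
)
from .postprocess import BinaryEFM, NumericEFM, normalize
from .rule_engine import Rule, parse_rule_line

MAX_BRUTE_FORCE_REACTIONS = 16


def _data_path(name: str) -> Path:
    return Path(resources.files("regefm").joinpath("data", name))


def fig1_network() -> MetabolicNetwork:
    """The worked-example network.

    The stoichiometric rows are a synthetic reconstruction from the
    published kernel (see the module docstring); the reaction list,
    reversibility, kernel, and EFM set are the authentic ones.
    """
    return read_network_tsv(_data_path("fig1_network_synthetic.tsv"))


def fig1_kernel(ext: ExtendedNetwork | None = None) -> KernelMatrix:
    """The published 12×6 kernel of the worked example's extended matrix."""
    if ext is None:
        ext = split_reversibles(fig1_network())
    return load_kernel(_data_path("fig1_kernel.tsv"), ext)


def fig1_rules(variant: str, net: MetabolicNetwork | None = None) -> list[Rule]:
    """Rule variants of the worked example's single regulatory interaction.

    ``"none"`` → no rules; ``"one_active"`` → ``R7r = NOT(1R9)``;
    ``"full_active"`` → ``R7r = NOT(fR9)``.
    """
    if net is None:
        net = fig1_network()
    texts = {
        "none": [],
        "one_active": ["R7r = NOT(1R9)"],
        "full_active": ["R7r = NOT(fR9)"],
    }
    try:
        lines = texts[variant]
    except KeyError:
        raise ValueError(f"unknown rule variant {variant!r}") from None
    return [parse_rule_line(t, net, rule_id=f"GR{i + 1}") for i, t in enumerate(lines)]


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_ext_supports(ext: ExtendedNetwork) -> list[frozenset[int]]:
    """All extended-network EFM supports (futile 2-cycles included).

    A support is elementary iff the null space of the support-restricted
    ``S_ext`` is one-dimensional and strictly sign-definite on the support.
    Supersets of found supports and strict supersets of futile pairs are
    skipped — they can never satisfy the one-dimensionality test.
    """
    n = ext.n_ext
    if n > MAX_BRUTE_FORCE_REACTIONS:
        raise ValueError(
            f"brute force refuses {n} extended reactions "
            f"(cap {MAX_BRUTE_FORCE_REACTIONS})"
        )
    pairs = [frozenset(cols) for cols in ext.col_map.values() if len(cols) == 2]
    max_size = rank(ext.S_ext) + 1 if ext.S_ext and ext.S_ext[0] else 1
    found: list[frozenset[int]] = []
    for size in range(1, min(n, max_size) + 1):
        for T in combinations(range(n), size):
            Ts = frozenset(T)
            if any(p < Ts for p in pairs):
                continue
            if any(s <= Ts for s in found):
                continue
            sub = [[row[c] for c in T] for row in ext.S_ext]
            basis = nullspace(sub, n_cols=size)
            if len(basis) != 1:
                continue
            v = basis[0]
            if all(x > 0 for x in v) or all(x < 0 for x in v):
                found.append(Ts)
    return found


def _merge_ext_support(
    support: frozenset[int], flux: dict[int, Fraction], ext: ExtendedNetwork
) -> NumericEFM:
    net = ext.base
    v = [Fraction(0)] * len(net.reactions)
    for j, rid in enumerate(net.reaction_ids):
        cols = ext.col_map[rid]
        v[j] += flux.get(cols[0], Fraction(0))
        if len(cols) == 2:
            v[j] -= flux.get(cols[1], Fraction(0))
    return NumericEFM(flux=tuple(v))


def brute_force_efms(ext: ExtendedNetwork) -> list[NumericEFM]:
    """Exhaustively enumerate the network's EFMs (merged, max-abs normalized).

    Futile 2-cycles are dropped; fully reversible modes appearing in both
    orientations are deduplicated by merged support.
    """
    pairs = {frozenset(cols) for cols in ext.col_map.values() if len(cols) == 2}
    efms: dict[int, NumericEFM] = {}
    for Ts in brute_force_ext_supports(ext):
        if Ts in pairs:
            continue
        cols = sorted(Ts)
        sub = [[row[c] for c in cols] for row in ext.S_ext]
        v = nullspace(sub, n_cols=len(cols))[0]
        if v[0] < 0:
            v = [-x for x in v]
        efm = _merge_ext_support(Ts, dict(zip(cols, v)), ext)
        mask = efm.support_mask()
        if mask not in efms:
            efms[mask] = NumericEFM(flux=normalize(efm.flux))
    return [efms[m] for m in sorted(efms)]


def brute_force_supports(ext: ExtendedNetwork) -> set[int]:
    """Merged EFM support masks from the brute-force enumerator."""
    return {e.support_mask() for e in brute_force_efms(ext)}


# ---------------------------------------------------------------------------
# Seeded random fixtures


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape of a generated network; seeded runs are bit-reproducible."""

    n_metabolites: int = 4
    n_reactions: int = 9
    reversible_fraction: float = 0.25
    coefficients: tuple[int, ...] = (1, 1, 1, 2)
    seed: int = 0


def generate_network(cfg: GeneratorConfig) -> MetabolicNetwork:
    """Random connected network with a guaranteed nontrivial flux cone.

    A backbone (uptake → chain of conversions → secretion) keeps every
    metabolite reachable; the remaining columns are random conversions.  The
    backbone needs ``n_reactions >= n_metabolites + 1``.
    """
    nm, nr = cfg.n_metabolites, cfg.n_reactions
    if nm < 1 or nr < nm + 1:
        raise ValueError("need n_reactions >= n_metabolites + 1 >= 2")
    rng = random.Random(cfg.seed)
    columns: list[list[Fraction]] = []

    def column(entries: dict[int, int]) -> list[Fraction]:
        col = [Fraction(0)] * nm
        for i, c in entries.items():
            col[i] += c
        return col

    columns.append(column({0: 1}))  # uptake of the first metabolite
    for i in range(nm - 1):  # conversion chain covering every metabolite
        columns.append(column({i: -rng.choice(cfg.coefficients),
                               i + 1: rng.choice(cfg.coefficients)}))
    columns.append(column({nm - 1: -1}))  # secretion of the last metabolite
    attempts = 0
    while len(columns) < nr:
        attempts += 1
        if attempts > 1000:
            raise ValueError("infeasible generator config: cannot place distinct columns")
        if nm == 1:
            col = column({0: rng.choice((-1, 1)) * rng.choice(cfg.coefficients)})
        else:
            a = rng.randrange(nm)
            b = (a + rng.randrange(1, nm)) % nm
            col = column({a: -rng.choice(cfg.coefficients),
                          b: rng.choice(cfg.coefficients)})
        if any(existing == col for existing in columns):
            continue
        columns.append(col)
    n_rev = int(cfg.reversible_fraction * nr)
    rev_idx = set(rng.sample(range(nr), n_rev)) if n_rev else set()
    reactions = [
        ReactionSpec(id=f"R{j + 1}", reversible=j in rev_idx) for j in range(nr)
    ]
    S = [[columns[j][i] for j in range(nr)] for i in range(nm)]
    return MetabolicNetwork(
        metabolite_ids=[f"M{i + 1}" for i in range(nm)], reactions=reactions, S=S
    )


def generate_rules(net: MetabolicNetwork, n_rules: int, seed: int = 0) -> list[Rule]:
    """Seeded ``X = NOT(aY)`` rules with activity a ∈ {1, f} and distinct
    reactions X, Y — the shape of typical glucose-repression mappings."""
    rng = random.Random(seed)
    ids = net.reaction_ids
    rules = []
    for k in range(n_rules):
        x, y = rng.sample(ids, 2)
        act = rng.choice(["1", "f"])
        rules.append(
            parse_rule_line(f"{x} = NOT({act}{y})", net, rule_id=f"GR{k + 1}")
        )
    return rules
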