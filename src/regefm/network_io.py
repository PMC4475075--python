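"""Metabolic network representation, tab-separated / SBML readers, and the
splitting of reversible reactions into irreversible forward/backward pairs.

A network is the internal stoichiometric matrix ``S`` (rows = internal
metabolites, columns = reactions) plus reaction identities and reversibility
flags.  External metabolites act as sources and sinks; they do not obey the
steady-state condition and are never part of ``S`` — open reaction ends stand
in for them.

The canonical interchange format is a small TSV dialect::

    #       R1      R2      ...
    #rev    0       1       ...
    M_A     1       -1      ...

Coefficients may be integers, decimals, or ``p/q`` rationals and are kept
exact end-to-end.  SBML (Level 2/3) is supported as a convenience reader;
species flagged ``boundaryCondition`` (or living in a caller-designated
external compartment) are dropped from ``S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._linalg import Matrix, format_rational, parse_rational


class NetworkFormatError(ValueError):
    """Raised for malformed network files or inconsistent network data."""


@dataclass(frozen=True)
class ReactionSpec:
    """A single reaction: short unique id, free-text name, reversibility."""

    id: str
    name: str = ""
    reversible: bool = False


@dataclass
class MetabolicNetwork:
    """Internal stoichiometric matrix with reaction metadata.

    ``S`` has one row per entry of ``metabolite_ids`` and one column per
    entry of ``reactions``; every column must touch at least one metabolite.
    """

    metabolite_ids: list[str]
    reactions: list[ReactionSpec]
    S: Matrix

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if not ids or not self.metabolite_ids:
            raise NetworkFormatError("empty network")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkFormatError(f"duplicate reaction ids: {dupes}")
        if any(not i for i in ids):
            raise NetworkFormatError("empty reaction id")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise NetworkFormatError("duplicate metabolite ids")
        if len(self.S) != len(self.metabolite_ids):
            raise NetworkFormatError(
                f"{len(self.S)} stoichiometry rows for "
                f"{len(self.metabolite_ids)} metabolites"
            )
        for row in self.S:
            if len(row) != len(self.reactions):
                raise NetworkFormatError("ragged stoichiometric matrix")
        for j, rxn in enumerate(self.reactions):
            if all(row[j] == 0 for row in self.S):
                raise NetworkFormatError(f"reaction {rxn.id} has an all-zero column")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id: {rid}") from None


@dataclass
class ExtendedNetwork:
    """All-irreversible network obtained by splitting reversible reactions.

    ``col_map`` sends each original reaction id to a 1-tuple (irreversible)
    or an ordered (forward, backward) pair of extended column indices; the
    backward column is the exact negation of the forward (= original) column
    and sits immediately after it.
    """

    base: MetabolicNetwork
    S_ext: Matrix
    col_map: dict[str, tuple[int, ...]]
    ext_reaction_ids: list[str] = field(default_factory=list)

    @property
    def n_ext(self) -> int:
        return len(self.ext_reaction_ids)

    def original_of(self, ext_index: int) -> str:
        """Original reaction id owning an extended column."""
        for rid, cols in self.col_map.items():
            if ext_index in cols:
                return rid
        raise KeyError(f"extended column {ext_index} unmapped")


def _split_ids(rxn: ReactionSpec, taken: set[str]) -> tuple[str, str]:
    """Forward/backward ids for a split reversible reaction.

    ``R7r`` becomes ``R7f``/``R7b``; ids without the trailing ``r`` get a
    bare ``f``/``b`` suffix (``R4`` -> ``R4f``/``R4b``); on collision an
    underscore is inserted.
    """
    stem = rxn.id[:-1] if rxn.id.endswith("r") and len(rxn.id) > 1 else rxn.id
    fwd, bwd = stem + "f", stem + "b"
    if fwd in taken or bwd in taken:
        fwd, bwd = rxn.id + "_f", rxn.id + "_b"
    return fwd, bwd


def split_reversibles(net: MetabolicNetwork) -> ExtendedNetwork:
    """Split each reversible reaction into an irreversible forward/backward
    pair by negating its column and appending the copy right after it."""
    taken = set(net.reaction_ids)
    ext_ids: list[str] = []
    col_map: dict[str, tuple[int, ...]] = {}
    columns: list[list[Fraction]] = []
    for j, rxn in enumerate(net.reactions):
        col = [row[j] for row in net.S]
        if rxn.reversible:
            fwd, bwd = _split_ids(rxn, taken)
            col_map[rxn.id] = (len(columns), len(columns) + 1)
            ext_ids += [fwd, bwd]
            columns.append(col)
            columns.append([-x for x in col])
        else:
            col_map[rxn.id] = (len(columns),)
            ext_ids.append(rxn.id)
            columns.append(col)
    S_ext = [[col[i] for col in columns] for i in range(len(net.metabolite_ids))]
    return ExtendedNetwork(base=net, S_ext=S_ext, col_map=col_map, ext_reaction_ids=ext_ids)


def merge_split_columns(ext: ExtendedNetwork) -> Matrix:
    """Recover ``S`` from ``S_ext`` by collapsing each forward/backward pair.

    The forward column equals the original and the backward column is its
    negation, so (forward − backward)/2 reproduces the original exactly.
    """
    rows = []
    for i in range(len(ext.base.metabolite_ids)):
        row = []
        for rid in ext.base.reaction_ids:
            cols = ext.col_map[rid]
            if len(cols) == 2:
                row.append((ext.S_ext[i][cols[0]] - ext.S_ext[i][cols[1]]) / 2)
            else:
                row.append(ext.S_ext[i][cols[0]])
        rows.append(row)
    return rows


def resplit_support(ext: ExtendedNetwork, original_support: Iterable[str]) -> set[int]:
    """Extended columns possibly active for a set of active original reactions."""
    out: set[int] = set()
    for rid in original_support:
        out.update(ext.col_map[rid])
    return out


# ---------------------------------------------------------------------------
# TSV dialect


def read_network_tsv(path: str | Path) -> MetabolicNetwork:
    lines = [
        ln.rstrip("\n")
        for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip()
    ]
    if len(lines) < 3:
        raise NetworkFormatError(f"{path}: need two header rows and >=1 metabolite row")
    head = lines[0].split("\t")
    rev = lines[1].split("\t")
    if head[0] != "#" or rev[0] != "#rev":
        raise NetworkFormatError(f"{path}: expected '#' and '#rev' header rows")
    rxn_ids = head[1:]
    rev_flags = rev[1:]
    if len(rev_flags) != len(rxn_ids):
        raise NetworkFormatError(f"{path}: reversibility row length mismatch")
    if any(f not in ("0", "1") for f in rev_flags):
        raise NetworkFormatError(f"{path}: reversibility flags must be 0/1")
    reactions = [
        ReactionSpec(id=rid, reversible=flag == "1")
        for rid, flag in zip(rxn_ids, rev_flags)
    ]
    met_ids: list[str] = []
    S: Matrix = []
    for ln in lines[2:]:
        parts = ln.split("\t")
        if len(parts) != len(rxn_ids) + 1:
            raise NetworkFormatError(
                f"{path}: metabolite row {parts[0]!r} has {len(parts) - 1} "
                f"coefficients, expected {len(rxn_ids)}"
            )
        met_ids.append(parts[0])
        try:
            S.append([parse_rational(x) for x in parts[1:]])
        except ValueError as exc:
            raise NetworkFormatError(f"{path}: bad coefficient in row {parts[0]!r}: {exc}")
    return MetabolicNetwork(metabolite_ids=met_ids, reactions=reactions, S=S)


def write_network_tsv(net: MetabolicNetwork, path: str | Path) -> None:
    out = ["#\t" + "\t".join(net.reaction_ids)]
    out.append("#rev\t" + "\t".join("1" if r.reversible else "0" for r in net.reactions))
    for mid, row in zip(net.metabolite_ids, net.S):
        out.append(mid + "\t" + "\t".join(format_rational(x) for x in row))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# SBML


def read_network_sbml(
    path: str | Path, external_compartments: Sequence[str] = ()
) -> MetabolicNetwork:
    """Read an SBML model, dropping boundary species from ``S``.

    Species with ``boundaryCondition=true`` or belonging to a compartment in
    ``external_compartments`` are treated as external sources/sinks.
    Stoichiometries are converted to rationals via their decimal notation.
    """
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text(encoding="utf-8"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise NetworkFormatError(f"{path}: SBML parse error")
    model = doc.getModel()
    if model is None:
        raise NetworkFormatError(f"{path}: no SBML model element")
    external = set(external_compartments)
    internal = [
        sp.getId()
        for sp in model.getListOfSpecies()
        if not sp.getBoundaryCondition() and sp.getCompartment() not in external
    ]
    index = {mid: i for i, mid in enumerate(internal)}
    reactions: list[ReactionSpec] = []
    columns: list[list[Fraction]] = []
    for rxn in model.getListOfReactions():
        col = [Fraction(0)] * len(internal)
        for ref in rxn.getListOfReactants():
            i = index.get(ref.getSpecies())
            if i is not None:
                col[i] -= Fraction(str(ref.getStoichiometry()))
        for ref in rxn.getListOfProducts():
            i = index.get(ref.getSpecies())
            if i is not None:
                col[i] += Fraction(str(ref.getStoichiometry()))
        if all(x == 0 for x in col):
            continue  # pure exchange reaction: only boundary species
        reactions.append(
            ReactionSpec(id=rxn.getId(), name=rxn.getName() or "", reversible=rxn.getReversible())
        )
        columns.append(col)
    used = [i for i in range(len(internal)) if any(col[i] != 0 for col in columns)]
    S = [[col[i] for col in columns] for i in used]
    return MetabolicNetwork(
        metabolite_ids=[internal[i] for i in used], reactions=reactions, S=S
    )


def read_network(path: str | Path, format: str | None = None, **kwargs) -> MetabolicNetwork:
    """Read a network from ``tsv`` or ``sbml`` (guessed from the suffix)."""
    if format is None:
        format = "sbml" if str(path).lower().endswith((".xml", ".sbml")) else "tsv"
    if format == "tsv":
        return read_network_tsv(path)
    if format == "sbml":
        return read_network_sbml(path, **kwargs)
    raise ValueError(f"unknown network format: {format!r}")
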