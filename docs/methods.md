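# Methods

## Model and scope

`regefm` enumerates elementary flux modes (EFMs) of a metabolic network
given as an internal stoichiometric matrix *S* (rows = internal metabolites,
columns = reactions) with per-reaction reversibility flags.  External
metabolites are assumed to be absent from *S*: open reaction ends act as
sources and sinks.  The package does **not** compress networks (dead-end
removal, enzyme-subset merging), handle flux bounds, or model continuous /
time-dependent regulation; rule files always refer to the uncompressed
reaction identifiers.

## Enumeration procedure

1. **Splitting.**  Every reversible column is duplicated with negated sign
   immediately after the original, giving the all-irreversible
   *S*<sub>ext</sub>.  Extended ids follow the `R7r → R7f/R7b`, `R4 →
   R4f/R4b` convention (an underscore variant is used on collision).
2. **Kernel.**  The initial mode matrix is a basis of the right null space
   of *S*<sub>ext</sub>, computed by exact Gauss–Jordan elimination with a
   fixed first-nonzero pivot rule, so the basis is deterministic for a given
   input.  A pre-computed kernel can be loaded instead (a null-space basis
   is not unique; loading reproduces published worked examples exactly) and
   is validated against *S*<sub>ext</sub>·*K* = 0.
3. **Ordering.**  Rows without negative entries are placed first (zeros are
   allowed: such rows are sign-decided and can be binarized immediately);
   the rest are sorted by increasing (#neg × #pos) adjacency-candidate
   count, with ties broken by original extended-column index so traces are
   reproducible.  With `--rulesort`, rows of reactions that participate in
   rules are moved directly behind the non-negative block (keeping their
   candidate-sorted relative order) so rule patterns become applicable as
   early as possible; rows inside the non-negative block never move.
4. **Iteration.**  One pending row per step is binarized.  Modes with
   negative pivot entries are dropped after pairing: each negative×positive
   pair passing the combinatorial adjacency test (no third mode's support
   contained in the union; a naive pairwise scan — bit-pattern trees are an
   optimization the desk-scale implementation does not need) contributes a
   child with OR-ed support and the weighted-subtraction tail.  Children are
   appended in (negative-parent, positive-parent) index order, another
   determinism choice.
5. **Rule pruning.**  Iteration-phase rules (expression definitely false at
   all-inputs-active, output defined at flux 1) are compiled to bit
   patterns: one pattern per assignment of forward/backward alternatives to
   reversible participants, with input and output reactions all set.  A
   pattern applies once all its reactions are binarized; matching modes are
   removed after each step, and once before iteration 1 (an initial basis
   mode can already match).  Pruning before or after child generation gives
   identical final sets — children of a matching mode match as well, by OR
   monotonicity — the tests assert the equivalent enumerate-then-filter
   identity.  Only the all-inputs-at-1 implication is compiled; partial
   input forcing is deliberately not exploited.
6. **Post-processing.**  Futile 2-cycles (support exactly one reversible
   pair) are removed; forward/backward bits are merged by OR; all rules are
   re-checked on the merged supports in three-valued semantics (a reversible
   reaction counts as active if either direction is); numeric fluxes are
   recovered and normalized to max |flux| = 1, matching the usual printed
   scale.  EFM columns are ordered lexicographically by support bits, since
   no canonical published order exists.

## Three-valued rule semantics

Atoms map flux bits to truth values through their activity tag (`0`/`1`/`f`);
an unsatisfied tag yields *undefined*.  Connectives follow Kleene's strong
three-valued logic (¬u = u, u∧false = false, u∧true = u, u∨true = true,
u∨false = u) — the standard completion, chosen because the semantics of the
rules only fix that an undefined evaluation withholds the rule.  A mode
violates a rule iff output and expression are both defined and differ;
multiple rules combine conjunctively.  Output atoms accept activity
prefixes like inputs (the grammar is uniform even though typical rule sets
tag only inputs).

## Numeric recovery

For a binary EFM, the kernel restricted to the rows of *inactive* reactions
gives a homogeneous system whose solution is the mode's flux direction.
With split reversibles the naive restriction is degenerate: whenever a
reversible reaction is active, the futile 2-cycle direction lies in the
kernel's span, inflating the coefficient space by one dimension per active
reversible.  The implementation therefore first merges each
forward/backward kernel row pair as forward − backward (annihilating the
cycle direction) and requires the *image in flux space* to be exactly
one-dimensional; anything else raises an elementarity error.  The sign is
fixed by the first active irreversible reaction (first nonzero entry for
all-reversible supports).  An independent second route — the null space of
*S* restricted to the active columns — is implemented as a cross-check and
asserted equal in the tests.

## Verification strategy

* **Worked example.**  The bundled 12-metabolite / 11-reaction fixture
  carries its published kernel verbatim.  Its stoichiometric rows are a
  *synthetic reconstruction* (the original matrix is not distributed with
  the package): six coprime integer vectors spanning the left null space of
  the kernel plus six dependent combinations standing in for redundant
  conservation relations.  Any matrix with this row space has the same flux
  cone and hence the same EFM set; the tests confirm the reconstruction
  reproduces the published 11 numeric EFMs, intermediate iteration states,
  and the 11 / 7 / 5 counts for the no-rule / 1-active / full-active rule
  variants.
* **Independent oracle.**  `oracle_fixtures.brute_force_efms` enumerates
  supports exhaustively and keeps those whose restricted null space is
  one-dimensional and sign-definite — a definition-level check sharing no
  code path with the iteration engine.  It prunes supersets of found
  supports and of futile pairs and caps problems at 16 extended reactions.
* **Randomized properties.**  Seeded random networks (4 metabolites, 9
  reactions, 25 % reversible — small enough for the exhaustive oracle,
  large enough to exercise splitting, adjacency, and pruning) are checked
  for: oracle equality, regulated run ≡ enumerate-then-filter, steady state
  (*S·e* = 0 exactly), irreversibility, pairwise support minimality, order
  invariance under random admissible row orders, and monotone rule strength
  (full-active ⊆ 1-active ⊆ unregulated).  The generator builds an
  uptake → conversion-chain → secretion backbone plus random two-metabolite
  conversions, guaranteeing connectivity and a nontrivial flux cone; it
  does not attempt biologically realistic stoichiometry, so the tests
  demonstrate algorithmic correctness, not model realism.  Genome-scale
  behaviour (memory, bit-pattern-tree adjacency, threading) is out of scope.

## Defaults worth knowing

| Parameter | Default | Why |
| --- | --- | --- |
| normalization | max-abs = 1 | matches the conventional printed scale |
| numeric output precision | 2 decimals | printed tables; internal values stay exact |
| rule activity (untagged) | full-active | the strictest, most informative reading |
| `--rulesort` | off | reordering only pays when rules prune many modes |
| generator shape | 4×9, 25 % reversible | ≤ 14 extended reactions keeps the exhaustive oracle fast |
| sweep limit | ≤ 12 rules | 2ⁿ pipeline runs |

Degenerate inputs: a 0-dimensional null space reports "no flux possible"
and yields an empty mode set; empty rule files parse to an empty list with
a warning; the zero vector cannot be normalized; `combine` insists on a
strict sign pair at the pivot.
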