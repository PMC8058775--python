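# Methods

This note documents the models and procedures implemented in rxnlint,
the choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Problem setting

A reaction network is a finite set of species and reactions
`r: Σ kᵢ·xᵢ -> Σ cⱼ·yⱼ` with positive rational stoichiometries. The
stoichiometry matrix `N` has one row per species and one column per
reaction; entry `(i, j)` is the net moles of species `i` produced by
reaction `j` (negative when consumed). Two structural error classes are
analysed:

* **Moiety imbalance** — per reaction. Species are decomposed into
  multisets of moieties (characteristic substructures whose instances
  may differ slightly in atomic formula, e.g. the three phosphates of
  ATP vs free inorganic phosphate). A reaction is moiety balanced when
  every moiety's stoichiometry-weighted count is equal on both sides.
  Moiety imbalance does not imply stoichiometric inconsistency (a
  single `ATP -> ADP` is unbalanced but consistent), nor conversely.
* **Stoichiometric inconsistency** — network-wide. The network is
  consistent iff a strictly positive mass vector `v` exists with
  `Nᵀv = 0`. Inconsistency means some species is forced to zero mass.

All analyses are static: no kinetics, rules or events are read, and
reversibility is ignored because mass-balance constraints are
direction-independent.

## Moiety resolution

Two conventions are supported, tried in order per species id:

1. underscore-separated names (`A_Pi_Pi_Pi` → {A:1, Pi:3}); empty
   tokens are malformed;
2. for each token not itself a known moiety, exact gap-free,
   case-sensitive concatenation against the user's moiety list,
   enumerated by dynamic programming over string positions.

A name may decompose in more than one way (`AB` over {A, B, AB}).
Decompositions are ordered fewest-moieties-first, then
lexicographically; the first is selected and the ambiguity is recorded
on the structure. This tie-break is a design choice: it prefers the
coarsest reading of a name, is deterministic, and is surfaced to the
user rather than silently guessed. Species that resolve no way are
collected as *unresolved* and reported as per-reaction diagnostics, not
fatal errors — a linter should degrade gracefully on partially
annotated models. Matching is exact-string with no stemming, because
balance checking must be deterministic.

Compartment tags that look like moieties (`_nuc`, `_sol`) are handled
by ignore lists in the configuration, not by parsing heuristics.
Non-integer stoichiometries produce exact rational deltas; any nonzero
delta is an imbalance.

## LP detection

Strict positivity cannot be expressed in an LP, so the scale-invariant
reformulation `vᵢ ≥ 1` is solved as a pure feasibility problem
(constant objective) with HiGHS. A returned witness is rescaled to
minimum component 1 and verified against `Nᵀv = 0` (tolerance 1e-9,
scaled by problem magnitude) before being reported; verification
failure is a distinct solver-error status, never silently
"consistent". An exact-rational cross-check (`lp.exact_consistency`)
eliminates the equality constraints by Gaussian elimination over
`fractions.Fraction` and decides the residual inequality system by
Fourier–Motzkin elimination; its cost grows quickly with null-space
dimension, which confines it to small matrices (the tests run it up to
~12 species).

## Graphical isolation

* Uni-uni reactions (one reactant, one product, equal stoichiometries)
  imply mass equality; union-find over these merges species into mass
  equivalence sets (MEQs). The union edges actually applied are kept as
  the MEQ's spanning reactions; redundant uni-unis are recorded
  separately.
* Multi-uni reactions (≥2 species on one side, one on the other) imply
  strict inequalities. With general stoichiometries `Σ kᵢ·xᵢ -> s·y`,
  the arc MEQ(x) → MEQ(y) is emitted only when `kₓ ≥ s`, which strictly
  implies mass(x) < mass(y); other terms are left to the algebraic
  stage rather than risking an unsound arc. One-to-one reactions with
  unequal stoichiometries (`k·A -> m·B`, k ≠ m) are treated as
  inequality arcs oriented toward the heavier side. An arc inside a
  single MEQ is an immediate contradiction and is kept as a self-arc.
* A directed cycle proves inconsistency. The finder returns a shortest
  cycle (self-arcs first, then BFS from each node in deterministic
  index order) to keep the isolation small.
* The RIS is the cycle's arc reactions plus, per traversed MEQ, the
  uni-uni reactions on a shortest path between the species where the
  cycle enters and leaves that MEQ — not every uni-uni of the MEQ,
  which keeps narratives minimal when an MEQ is large. The SIS is
  restricted to members of traversed MEQs that occur in RIS reactions.
  The narrative has three parts: equality lines, inequality lines, and
  a closing `mass(x) < … < mass(x)` contradiction.

Graphical analysis is sound but incomplete: it never inspects
multi-multi reactions, so a class of real inconsistencies is invisible
to it (the near-duplicate-reaction fixtures below are constructed to
sit exactly in that gap).

## Algebraic isolation

The MEQ-level matrix replaces species rows by MEQ rows (summing), drops
uni-uni columns (their content is encoded in the MEQs), and drops
columns that cancel to zero at MEQ level (balanced by the equalities;
logged). `Nᵀ` is factored as `P·L·U` with partial pivoting and carried
on to reduced row echelon form while accumulating every row operation
in a transform `M`; transposing gives the reduced column echelon form
`R = N·C` with `C = Mᵀ` invertible. The identity `N·C = R` and the PLU
factorization are asserted inside the routine on every call — the
algorithm refuses to return an unverified decomposition.

All echelon arithmetic is exact rational. This is deliberate: matrix
reductions on stoichiometry matrices are prone to near-singularity, and
a linter that fabricates errors from round-off is worse than none.

Detection criteria: a nonzero column of `R` whose nonzero entries share
one sign describes a pseudo reaction with products and no reactants
(mass creation) or the reverse (destruction) — constructed from
supposedly balanced reactions, a contradiction. Because the echelon
normalization can negate a column, violations are reported in the
canonical orientation where the leading combination multiplier is
positive (r and −r describe the same inconsistency). When several
columns qualify, the one with the fewest combination terms is reported
(smallest RIS), ties by column order. The explanation is a three-step
proof by contradiction: MEQ equalities, the pseudo reactions involved,
and the rational combination with its reactant-free (or product-free)
net reaction, multipliers printed as reduced fractions.

Pivoting is deterministic — largest absolute rational value, ties to
the lowest original row index. Different permutations can surface
different errors, so optional re-runs shuffle pivot tie groups with a
seeded generator and report distinct isolations; soundness holds under
every permutation (the reduced form is unique; only the combinations
differ).

The same-sign criterion is sufficient but not necessary, so the staged
pipeline (LP → graphical → algebraic) reports an explicit
`inconsistent-not-isolated` verdict rather than forcing an answer; LP
remains the detector of record.

## Synthetic data

The generator assigns each species a hidden positive integer vector
over k moieties (k uniform in 2..5, entries 1..3) and emits only
reactions that conserve those vectors exactly — a mix of uni-uni pairs
(duplicated vectors), multi-uni triples (vector sums; one such triple
and its reaction are always present when the species count allows, so
error injectors always have a target), and greedily solved conserving
reactions (retry budget 100, integer stoichiometries ≤ 3). Any positive
functional of the vectors is then a strictly positive mass witness, so
generated networks are simultaneously LP-consistent and moiety
balanced; one generator exercises both subsystems. Hidden-vector
construction was chosen over random mass assignment precisely for this
double guarantee.

Error injectors create ground-truthed failures:

* *cycle_error*: a uni-uni back-edge `y -> x` across a multi-uni
  `x + … -> y` (chosen so the stoichiometry condition above makes the
  inequality strict) — guaranteed MEQGraph cycle, provably
  LP-infeasible;
* *dc_error*: a near-duplicate of a multi-uni with one qualifying
  reactant stoichiometry incremented. The difference of the two columns
  is a pure destruction column, so the standard-basis vector of that
  MEQ lies in the column space and the reduced form must expose it —
  while no new equality or inequality relation appears, keeping the
  graph acyclic. This class is therefore caught by the algebraic stage
  and missed by the graphical one, by construction;
* *moiety_drop*: one product occurrence deleted; flags exactly that
  reaction with a negative delta equal to the dropped species' hidden
  vector, and may leave the network LP-consistent (moiety imbalance and
  stoichiometric inconsistency are different errors).

What passing tests on these fixtures shows: soundness (no false
positives on conserving networks), exactness of the echelon identity,
and complete recovery of the injected reaction in the RIS for both
error classes. What they do not show: behaviour on real curated models
— synthetic networks are small (≤ ~12 species), have unit-to-3
stoichiometries, no boundary species, no compartment naming noise, and
error classes planted one at a time. Corpus-wide coverage fractions and
RIS-size averages depend on whichever model collection is on disk;
`rxnlint.batch` recomputes them for any local directory, but they are
not reproducible from this repository alone and are not asserted
anywhere.

## Problem sizes and numerics

The test suite measures soundness over 1000 seeded networks (4–12
species) and recovery over 200 seeded injections per error class;
`scripts/acceptance.py` uses 400 and 200 with seeds derived from its
`--seed` argument. These sizes keep a full run in seconds while giving
rate estimates at the percent level. LP tolerance is 1e-9 (scaled);
everything downstream of LP is exact rational, so no other tolerances
exist. Degenerate inputs (empty networks, zero matrices, identity
reactions `A -> A`, rank-deficient MEQ matrices) are valid and return
consistent/empty results rather than errors.

## Known limitations

* Balance is checked in units of moieties and of abstract mass only;
  atomic-formula balance (via chemical annotations) and charge balance
  are out of scope.
* The SBML reader covers species, reactions and stoichiometries;
  kinetic laws, rules, events, annotations and compartment-volume
  semantics are ignored.
* One isolation is reported per run (plus optional permutation
  re-runs); the tool does not enumerate all errors in a model.
* The graphical stage's arc rule is conservative under non-unit
  stoichiometries; some cycles expressible with fractional reasoning
  are deferred to the algebraic stage.
* Numeric repetition shorthands in species names (e.g. `p2` for `pp`)
  are not interpreted; only plain concatenation and underscore
  separation are.
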