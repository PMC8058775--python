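# rxnlint

A static linter for biochemical reaction networks. It finds — and, more
importantly, *isolates* — structural errors in reaction-based models
(SBML or a plain-text dialect) without running any simulation:

* **moiety imbalances**: a reaction that should conserve chemical
  substructures (moieties such as inorganic phosphate `Pi`, adenosine
  `A`, a phospho group `p`) but doesn't — e.g. ATP hydrolysis written as
  `ATP -> ADP`, which silently loses a phosphate;
* **stoichiometric inconsistencies**: a network structure that admits
  *no* assignment of strictly positive masses `v` with `Nᵀv = 0`, where
  `N` is the stoichiometry matrix — i.e. some species is forced to have
  zero mass.

It is aimed at modelers curating or reusing reaction-based models
(signalling, regulatory and metabolic networks), where detection alone
is not enough: an error buried in hundreds of reactions is only fixable
once a small set of implicated reactions (the reaction isolation set,
RIS), species (SIS) and a human-checkable explanation are in hand.

## How it works

**Moiety analysis** resolves each species id into a multiset of
moieties, either by underscore convention (`A_Pi_Pi_Pi` → {A:1, Pi:3})
or by exact gap-free decomposition against a user-supplied moiety list
(`MEKpp` → {MEK:1, p:2}), then checks per reaction that every moiety's
stoichiometry-weighted count matches between reactants and products.

**LP analysis** detects inconsistency by solving the feasibility
problem `{Nᵀv = 0, vᵢ ≥ 1}` (equivalent to `v > 0` by scale
invariance). It is the detector of record but explains nothing.

**Graphical isolation** builds mass equivalence sets (MEQs) from
uni-uni reactions (`A -> B` forces mass(A) = mass(B), closed under
transitivity) and a digraph over MEQs from multi-uni reactions
(`a + b -> c` forces mass(a) < mass(c) and mass(b) < mass(c)). A
directed cycle proves some mass is smaller than itself; the cycle's
arcs plus the uni-uni chains inside the traversed MEQs form the RIS,
and a three-part narrative (equalities, inequalities, contradiction)
explains the error.

**Algebraic isolation** handles the errors the graph cannot see. The
MEQ-level stoichiometry matrix `N` is transformed to reduced column
echelon form `R = N·C` in exact rational arithmetic (`fractions`;
floats never enter, so near-singular matrices cannot produce false
detections). Every column of `R` is a *pseudo reaction* — an explicit
linear combination of model reactions. A nonzero column whose nonzero
entries share one sign is a constructive proof of mass creation or
destruction, and the combination read off `C` is the RIS.

The staged pipeline runs LP → graphical → algebraic, and reports an
honest `inconsistent-not-isolated` verdict for the residual coverage
gap (the same-sign criterion is sufficient, not necessary).

## Worked example

A STAT-dimerization model in the text dialect (`stat_dimer.rxn`) with
a spurious `species_test` product on R3:

```
R3: Pstat_nuc -> species_test + Pstat_sol
R1: 2 Pstat_sol -> PstatDimer_sol
R4: 2 Pstat_nuc -> PstatDimer_nuc
R2: Pstat_nuc -> stat_nuc
R5: stat_nuc -> stat_sol
R6: PstatDimer_sol -> PstatDimer_nuc
```

```
$ rxnlint games stat_dimer.rxn
isolated
RIS: R3, R1, R4, R2, R5, R6
SIS: PstatDimer_nuc, PstatDimer_sol, Pstat_nuc, Pstat_sol, species_test, stat_nuc, stat_sol
Step 1: mass(Pstat_nuc) = mass(stat_nuc) by R2, so MEQ {Pstat_nuc=stat_nuc=stat_sol}
Step 1: mass(stat_nuc) = mass(stat_sol) by R5, so MEQ {Pstat_nuc=stat_nuc=stat_sol}
Step 1: mass(PstatDimer_sol) = mass(PstatDimer_nuc) by R6, so MEQ {PstatDimer_nuc=PstatDimer_sol}
Step 2: PR3: {Pstat_nuc=stat_nuc=stat_sol} -> {species_test} + {Pstat_sol}  (from R3)
Step 2: PR1: 2 {Pstat_sol} -> {PstatDimer_nuc=PstatDimer_sol}  (from R1)
Step 2: PR4: 2 {Pstat_nuc=stat_nuc=stat_sol} -> {PstatDimer_nuc=PstatDimer_sol}  (from R4)
Step 3: 1*PR3 + 1/2*PR1 - 1/2*PR4 =  -> {species_test}  — mass is created: contradiction
```

Reading it: Step 1 lists the uni-uni reactions that force the mass
equalities; Step 2 restates the remaining reactions over MEQs as
pseudo reactions; Step 3 exhibits the rational combination
`PR3 + ½·PR1 − ½·PR4` whose net effect is a reaction with products and
no reactants — mass from nothing, so the model cannot be mass
balanced. Exit code 1 signals findings (0 clean, 2 errors).

A moiety check needs only a moiety list:

```
$ rxnlint moiety kinase.rxn --moieties MAPK,MEK,p
1 reactions with moiety imbalance

reaction Reaction19a: MAPK + MEKpp -> MEKpp
  moiety MAPK: reactants 1, products 0 (delta -1)
```

— one missing MAPK, rather than an accounting of the ~3000 atoms a
per-atom balance check would report for a kinase that size.

Other subcommands: `rxnlint lint` (full battery + JSON report),
`rxnlint lp` (detection only, prints a positive mass witness when one
exists), `rxnlint fixtures` (seeded synthetic networks with ground
truth), `rxnlint batch` (coverage/RIS statistics over a directory of
models).

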