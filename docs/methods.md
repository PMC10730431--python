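# Methods

## The model class

`malatnet` implements multivalued logical models: each node carries a
small integer level (`0..max_level`; almost all nodes here are Boolean)
and each non-input node has a monotone logical rule over threshold
literals `Name:k` (true iff the level of `Name` is at least `k`).
Multilevel targets use guarded case expressions evaluated first-match with
descending levels. The signed regulatory graph is *derived* from the
rules: a regulator's sign is its semantic monotone effect on the target's
image, established by exhaustive scan over the contexts of the remaining
regulators, and its threshold is the smallest level step at which the
effect appears. Non-monotone or vacuous regulators are validation errors,
as is a mismatch between a literal's syntactic polarity (activators
un-negated, inhibitors negated) or a declared interaction sign and the
derived sign.

Dynamics are unitary asynchronous: a transition changes exactly one node
by exactly one level toward the value its rule prescribes. Every state
therefore has one successor per unstable node, stable states are exactly
the fixed points of the synchronous image, and attractors are the
terminal strongly connected components of the state-transition graph
(STG).

## The NSCLC network

The shipped model couples the MALAT1/miR-145/BMI1 axis to the DNA-damage
response and the G1/S machinery: one Boolean input (`DNA_damage`),
27 signaling components, 85 direct interconnections. `p53` is ternary —
level 1 is the arrester regime (p53-A, drives p21 and senescence), level
2 the killer regime (p53-K, drives BAX and apoptosis). Every
literature-documented interaction carries its provenance in
`interactions.csv`; the four phenotype reporters (Proliferation,
DrugResistance, Senescence, Apoptosis) read marker combinations and
regulate nothing.

The wild-type system has exactly four stable states and no other
attractor we can detect: proliferation with the input OFF, and — with the
input ON — drug resistance (MALAT1/Sp1/KLF4 active, p53 and miR-145
silent), senescence (p53-A with p21) and apoptosis (p53-K with
BAX/caspase-3). The resistant state is a self-sustaining shield: Sp1
keeps MALAT1 high, MALAT1 silences the p38 arm of p53 activation and
sponges miR-145, Myc keeps BMI1 high, and BMI1 holds ATM (the other p53
arm) off. The senescence/apoptosis pair is the bistable readout of the
p21/caspase-3 mutual antagonism together with the p53 level: p21 holds
p53 in the arrester regime, caspase-3 removes p21 and lets p53 reach the
killer level.

Design choices where the published description leaves the wiring open
(the exact per-node rules are not printed; the model is a reconstruction
calibrated against every printed constraint simultaneously — component
and edge counts, the four endpoints and their markers, the mutant
outcomes, and the functional-circuit counts):

- **p21 ⊣ p53 (arrester dominance).** Every other restrainer of the killer
  regime (Wip1, KLF4, Sirt1, Mdm2) is itself a miR-145 target, and
  miR-145 is active in both death endpoints; p21 is the only
  miR-145-independent node that can hold p53 at the arrester level, and
  without this edge no senescence fixed point exists.
- **MALAT1 gates only the p38 arm of p53 activation; BMI1 gates the ATM
  arm.** This makes the resistant state depend on both sponges at once,
  so knocking out either MALAT1 or BMI1 collapses resistance, as the
  knockdown experiments require.
- **Killer-p53 bypass on miR-145.** At level 2, p53 drives miR-145 past
  the MALAT1/BMI1 sponges; without it, clamping p53 at its maximum leaves
  an inert resistant state instead of the published apoptotic outcome.
- **Sp1 co-activates Mdm2 and Wip1** (Sp1 sites on the MDM2 promoter are
  documented); this lets the miR-145/Sp1/MALAT1 triple knockout reach
  p53-K/BAX apoptosis rather than oscillating on the p53/Mdm2 and
  p53/Wip1/p38 negative circuits.
- **BMI1 acts on Sp1 and KLF4 through miR-145 relief**, not by direct
  edges, matching the experimental chain (BMI1 ⊣ miR-145 ⊣ Sp1/KLF4); the
  Myc–E2F1 and ATM–E2F1 couplings are encoded as Myc→E2F1 and ATM→E2F1;
  RB1 inactivation is carried by the CDK4/6–CyclinD arm. These choices are
  what keeps the functional-circuit census at the published 30/21 — denser
  variants we explored carry 45–130 functional circuits.
- **BAX ⊣ Bcl2 mutual antagonism and p38→caspase-3** complete the death
  module so that the apoptotic state is unique (no spurious fixed point
  with p21 and killer p53 coexisting).

Two published grid claims are irreproducible in this formalism and are
left failing in the acceptance suite rather than masked: a fixed
point consistent with a clamp persists under that clamp, so "Sp1 E1 gives
apoptosis only" cannot hold while the resistant endpoint itself carries
active Sp1; and partner clamps that pin p21's documented repressors
(Myc, BMI1) or pin the ternary p53 at one level remove one side of the
senescence/apoptosis pair.

## Algorithms

- **Stable states** are enumerated exactly by a pruned backtracking sweep:
  nodes are assigned in an order that completes each node's stability
  check as early as possible, and every completed check prunes the branch.
  The 28-node network (3·2^27 ≈ 4·10^8 states) sweeps in well under a
  second.
- **Attractors**: below a configurable bound (default 2^22 states) the
  full STG is analyzed by an iterative Tarjan scan over the implicit
  graph, which is exact. Above it, cyclic attractors are sought by
  bounded breadth-first exploration from configurable initial states
  (default: the all-zero state per input combination); a terminal SCC
  found there is always genuine, but completeness is flagged, since the
  damage-ON reachable space of the NSCLC model exceeds 8.6 million
  states. All four wild-type attractors are stable, and no cyclic
  attractor appears within the explored regions.
- **Circuits** are enumerated with a length-bounded Johnson-style search
  (via `networkx.simple_cycles`), canonicalized to the lexicographically
  minimal rotation. A circuit is *functional* when the local
  functionality conditions of all its edges — raising the source across
  its acting threshold moves the target's image in the edge's sign
  direction — are simultaneously satisfiable over the union of the
  targets' other regulators. Satisfiability is decided by a backtracking
  join of per-edge witness sets; exact witness counts are enumerated only
  when the joint space is small.
- **Monte Carlo**: trajectories pick one enabled unitary transition
  uniformly at random per step; absorption is detected on stable states
  and on membership in supplied cyclic attractors, with censoring at
  `max_steps` (default 10,000). The default initial condition is the
  wild-type proliferation state with the damage input switched ON — a
  cycling cell receiving drug-induced damage — with uniform random
  initial states as the alternative mode. The default run count is
  10,000, and a bistability scenario is called resistance-reducing iff
  the apoptotic probability strictly exceeds 70%.

## The synthetic-model generator

`random_model` emulates the structural class the engine assumes: sparse
signed graphs (configurable node count, in-degree bound, multivalued
fraction, inhibitor fraction, seed) with monotone rules of the form
"OR of activators AND NOT (OR of inhibitors)", which are sign-consistent
by construction. The generator exists to make every engine component
testable against independent brute-force oracles (explicit-STG terminal
SCCs; full-state-scan circuit functionality) with exact set equality over
100-seed batteries. It does not emulate biological degree distributions,
autoregulation frequencies, or the long-tailed in-degrees of curated
networks, so passing batteries certify the algorithms, not any biological
realism of random instances.

## Numerical and engineering notes

- States are tuples in the model file's node order; the packed index is
  the mixed-radix encoding in that order, so state indices are
  reproducible across runs.
- Rules are compiled once per model into plain Python expressions; the
  sweep, exploration, and samplers all share the compiled image.
- Grid and validation analyses use a 20,000-state exploration bound per
  perturbation for cyclic detection (the outcome tables flag
  completeness); stable phenotypes are exact regardless of the bound.
- All reports embed the run configuration, package version, and seed, and
  JSON is written with sorted keys so identical configurations reproduce
  byte-identical files.

## Limitations

- Cyclic attractors of the full NSCLC model outside the explored regions
  cannot be excluded; the published analysis reports oscillations only in
  a few perturbed cases, which is consistent with what bounded
  exploration finds, but the package makes no completeness claim above
  the exact-analysis bound.
- The rule reconstruction is constrained by the printed counts and
  outcomes, not uniquely determined by them; alternative rule sets
  satisfying the same constraints may exist.
- Only unitary asynchronous updating is implemented; priority classes and
  continuous-time semantics are out of scope.
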