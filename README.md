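# malatnet

Asynchronous multivalued logical modeling of the MALAT1 / miR-145 / BMI1
drug-resistance axis in non-small cell lung cancer (NSCLC).

Chemoresistant NSCLC cells keep the tumor-suppressive microRNA miR-145
silenced through two sponges — the lncRNA MALAT1 (itself driven by Sp1)
and the polycomb protein BMI1 (driven by Myc) — while miR-145, when
active, dismantles the resistant program by targeting Sp1, KLF4, Myc,
Sirt1, Mdm2, Wip1, cyclin D and Bcl2. `malatnet` encodes this mechanism,
coupled to the ATM/p53 DNA-damage response and the G1/S machinery, as a
logical model — 1 input, 27 components, 85 interactions, with a ternary
p53 (0 = off, 1 = arrester p53-A, 2 = killer p53-K) — and provides the
analysis engine around it:

- **Formalism** (`malatnet.model`): monotone multivalued rules with
  threshold literals; the signed regulatory graph, edge signs and acting
  thresholds are derived from the rules and validated for
  sign consistency.
- **Dynamics** (`malatnet.dynamics`): unitary asynchronous updating,
  exact stable-state enumeration by a pruned backtracking sweep (no state
  space enumeration), exact attractors below a size bound, bounded
  terminal-SCC search above it.
- **Circuits** (`malatnet.circuits`): elementary-cycle enumeration, sign
  classification (positive = even number of inhibitions), and circuit
  *functionality* — simultaneous satisfiability of every edge's local
  sign-directional effect — which is what separates decorative loops from
  circuits that actually shape the dynamics.
- **Perturbations** (`malatnet.perturbation`): gain-of-function (E1) /
  loss-of-function (KO) clamps, phenotype calls from marker patterns,
  the published mutant validation suite, and circuit-perturbation grids.
- **Monte Carlo** (`malatnet.montecarlo`): random asynchronous
  trajectories from a damaged proliferating cell, phenotype probability
  estimates, and the strict >70 % apoptosis rule for resolving
  senescence/apoptosis bistability.
- **Synthetic models** (`malatnet.synthetic`): a seeded random-model
  generator and brute-force oracles (explicit STG, full-state
  functionality scan) against which the engine is tested with exact set
  equality.

## Worked example

```python
from malatnet import (
    Attractor, build_nsclc_model, classify_attractor, load_marker_map,
    phenotype_probabilities, classify_bistability, stable_states,
)
from malatnet.circuits import functional_circuit_census

model = build_nsclc_model()
markers = load_marker_map()

for s in sorted(stable_states(model)):
    call = classify_attractor(markers, Attractor("stable", frozenset([s])), model)
    print(call.label, "->", {k: v for k, v in model.state_dict(s).items() if v})

census = functional_circuit_census(model)
print("functional circuits:", census.total_functional,
      "| with <= 4 components:", census.n_functional_short)

dist = phenotype_probabilities(model, markers, {"miR-145": "E1"}, n_runs=10000, seed=1)
print("miR-145 E1:", dist.probabilities, "->", classify_bistability(dist))
```

prints

```
Proliferation -> {'MALAT1': 1, 'BMI1': 1, 'Sp1': 1, 'KLF4': 1, 'Myc': 1, ...}
DrugResistance -> {'DNA_damage': 1, 'p38MAPK': 1, 'MALAT1': 1, 'BMI1': 1, 'Sp1': 1, ...}
Senescence -> {'DNA_damage': 1, 'ATM': 1, 'p38MAPK': 1, 'p53': 1, 'miR-145': 1, 'RB1': 1, 'p21': 1, ...}
Apoptosis -> {'DNA_damage': 1, 'ATM': 1, 'p38MAPK': 1, 'p53': 2, 'miR-145': 1, 'RB1': 1, 'BAX': 1, 'Caspase3': 1, ...}
functional circuits: 30 | with <= 4 components: 21
miR-145 E1: {'Apoptosis': 0.3328, 'Senescence': 0.6672} -> supports_resistance
```

The four wild-type attractors are the model's endpoints: without DNA
damage the cell proliferates; with damage it either mounts the
MALAT1/Sp1/KLF4 resistant shield (p53 and miR-145 stay off), arrests in
senescence (arrester p53 with p21), or dies (killer p53 with
BAX/caspase-3). The census counts 30 functional feedback circuits, 21 of
them with at most four components — among them the four novel positive
circuits miR-145/Sp1/MALAT1, BMI1/miR-145/Myc, KLF4/p53/miR-145 and
miR-145/Wip1/p38MAPK/p53. Forcing miR-145 ON removes the resistant
attractor and leaves a senescence/apoptosis coin-flip whose apoptotic
share (here ≈ 33 %) stays under the 70 % threshold, so this scenario
alone is not called resistance-reducing.

## Command line

```
malatnet validate                 # counts + sign-consistency report
malatnet attractors               # stable states & bounded cyclic search
malatnet circuits                 # functional-circuit census (JSON)
malatnet perturb -p "BMI1=KO"     # phenotypes of a clamp combination
malatnet montecarlo -p "miR-145=E1" --n-runs 10000 --seed 1
malatnet analyze --out out/       # the full pipeline with JSON/CSV reports
malatnet export --out out/        # GraphML + edge-list CSV + attractors
malatnet simulate-random          # synthetic battery vs brute-force oracle
```

`--model path/to/file.rules` points any command at another model in the
same grammar (one line per node:
`Name, max_level[, input|output] : expression`, literals `Name` /
`Name:k`, operators `& | !`, guarded multilevel cases
`{2 if ...; 1 if ...; else 0}`).

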