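# Phenotype marker patterns: a stable state is assigned the (unique) label
# whose marker levels it matches exactly; cyclic attractors are labeled
# Oscillation.  p53 levels: 1 = arrester (p53-A), 2 = killer (p53-K).
Proliferation:
  DNA_damage: 0
  Myc: 1
  Sp1: 1
  CyclinD: 1
  CDK2: 1
DrugResistance:
  DNA_damage: 1
  MALAT1: 1
  Sp1: 1
  KLF4: 1
  p53: 0
  miR-145: 0
Senescence:
  p53: 1
  p21: 1
  Caspase3: 0
Apoptosis:
  p53: 2
  BAX: 1
  Caspase3: 1
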