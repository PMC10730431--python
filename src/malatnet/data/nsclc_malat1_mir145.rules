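# NSCLC drug-resistance network: the MALAT1 / miR-145 / BMI1 axis coupled
# to the DNA-damage response and the G1/S machinery.
# One Boolean input (DNA_damage) plus 27 signaling components; p53 is
# ternary (0 = off, 1 = arrester p53-A, 2 = killer p53-K), all other nodes
# Boolean.  Per-edge provenance lives in interactions.csv.

DNA_damage, 1, input

# DNA-damage response.  BMI1 shields ATM; MALAT1 silences the p38 arm of
# p53 activation, so the resistant state keeps p53 off on both routes.
ATM, 1 : DNA_damage & !BMI1
p38MAPK, 1 : (ATM | DNA_damage) & !Wip1
p53, 2 : {2 if (ATM | (p38MAPK & !MALAT1)) & !Mdm2 & !Wip1 & !KLF4 & !p21; \
          1 if (ATM | (p38MAPK & !MALAT1)) & !Mdm2 & (Wip1 | KLF4 | p21); else 0}
Mdm2, 1 : p53 & Sp1 & !miR-145
Wip1, 1 : p53 & Sp1 & !miR-145

# the ncRNA axis: killer p53 (level 2) induces miR-145 past the
# MALAT1/BMI1 sponges; arrester p53 needs both sponges off
miR-145, 1 : {1 if p53:2 | (p53 & !MALAT1 & !BMI1); else 0}
MALAT1, 1 : Sp1
BMI1, 1 : Myc
Sp1, 1 : !miR-145
KLF4, 1 : Sp1 & !miR-145

# stemness / chromatin
Myc, 1 : !miR-145
Sirt1, 1 : (E2F1 | HDAC1) & !miR-145
HDAC1, 1 : Sirt1 & Myc

# G1/S machinery
E2F1, 1 : (Myc & (!RB1 | !Sirt1)) | (ATM & !RB1 & !Sirt1)
RB1, 1 : !CDK4_6
CyclinD, 1 : (Myc | E2F1) & !miR-145 & !p21
CDK4_6, 1 : CyclinD
CyclinE, 1 : E2F1 | Myc
CDK2, 1 : CyclinE & !p21

# arrest and death effectors
p21, 1 : p53 & !Myc & !HDAC1 & !BMI1 & !Caspase3
Bcl2, 1 : Sp1 & !miR-145 & !BAX
BAX, 1 : p53:2 & !Bcl2
Caspase3, 1 : BAX & (p38MAPK | !p21)

# phenotype reporters
Proliferation, 1, output : E2F1 & Myc & CyclinD & CDK4_6 & CyclinE & CDK2 & !RB1 & !DNA_damage
DrugResistance, 1, output : DNA_damage & MALAT1 & Sp1 & KLF4 & !p53 & !miR-145
Senescence, 1, output : p53 & p21 & RB1 & !Caspase3 & !BAX & !CDK2
Apoptosis, 1, output : p53:2 & BAX & Caspase3 & p38MAPK & !Bcl2 & !p21
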