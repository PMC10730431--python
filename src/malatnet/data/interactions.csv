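source,target,sign,citation,note
p53,miR-145,+,[30],p53 transactivates miR-145
MALAT1,miR-145,-,[1],MALAT1 sponges miR-145
BMI1,miR-145,-,[2],BMI1 represses miR-145
miR-145,Sp1,-,[2],miR-145 targets Sp1
miR-145,KLF4,-,[1],miR-145 targets KLF4
miR-145,Myc,-,[4],miR-145 targets Myc
miR-145,CyclinD,-,[4],miR-145 targets the CDK4/6-Cyclin D module
miR-145,Bcl2,-,[5],miR-145 targets Bcl2
miR-145,Sirt1,-,[25],miR-145 targets Sirt1
miR-145,Mdm2,-,[24],miR-145 targets Mdm2
miR-145,Wip1,-,[50],miR-145 targets Wip1
Sp1,MALAT1,+,[3],Sp1 induces MALAT1 transcription
MALAT1,p53,-,[26],MALAT1 suppresses p53 activation
Myc,BMI1,+,[31],Myc transactivates BMI1
BMI1,ATM,-,[33],BMI1 inhibits ATM
BMI1,p21,-,[34],BMI1 inhibits p21
KLF4,p53,-,[32],KLF4 inhibits p53
p53,Mdm2,+,[46],p53 transactivates Mdm2
Mdm2,p53,-,[46],Mdm2 degrades p53
p53,Wip1,+,[47],p53 transactivates Wip1
Wip1,p53,-,[47],Wip1 dephosphorylates p53
Wip1,p38MAPK,-,[48],Wip1 dephosphorylates p38 MAPK
p38MAPK,p53,+,[48],p38 MAPK phosphorylates and activates p53
p21,Caspase3,-,[35],p21 blocks caspase-3 activation
Caspase3,p21,-,[35],caspase-3 cleaves p21
Sirt1,HDAC1,+,[36],Sirt1 sustains HDAC1
HDAC1,Sirt1,+,[36],HDAC1 sustains Sirt1
E2F1,Sirt1,+,[49],E2F1 induces Sirt1
Sirt1,E2F1,-,[49],Sirt1 deacetylates and inhibits E2F1
Myc,E2F1,+,[38],Myc-E2F1 coupling: Myc induces E2F1
ATM,E2F1,+,[39],ATM-E2F1 coupling: damage signaling stabilizes E2F1
Myc,p21,-,[40],Myc represses p21
HDAC1,p21,-,[21],HDAC1 represses p21
p53,p21,+,[41],p53 transactivates p21 at the G1/S checkpoint
CDK4_6,RB1,-,[37],CDK4/6-Cyclin D phosphorylates and inactivates RB1
RB1,E2F1,-,[42],hypophosphorylated RB1 sequesters E2F1
p53,BAX,+,[41],killer p53 (p53-K) transactivates BAX
Bcl2,BAX,-,[5],Bcl2 neutralizes BAX
BAX,Caspase3,+,[5],BAX triggers caspase-3 activation
DNA_damage,ATM,+,[21],DNA damage activates ATM
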