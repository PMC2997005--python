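Isl1
Hlxb9
Hex
Prox1
Hnf1b
Hnf6
Ptf1a
Pdx1
Pbx1
Sox9
Sox4
GATA-4
GATA-6
Ngn3
NeuroD1
Insm1
Myt1
Pax6
Pax4
Nkx2.2
Nkx6.1
MafA
MafB
Foxa1
Foxa2
HNF1a
HNF4a
TCF7L2
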