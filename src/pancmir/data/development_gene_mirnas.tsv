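gene_id	source	mirna_id	group
Isl1	MIRBASE	miR-182	II
Isl1	TARGETSCAN	miR-382	II
Isl1	TARGETSCAN	miR-432	II
Prox1	MIRBASE	miR-181b	II
Prox1	MIRBASE	miR-181d	II
Prox1	TARGETSCAN	miR-125a	II
Prox1	TARGETSCAN	miR-218	II
Sox9	TARGETSCAN	miR-130b	II
Sox9	TARGETSCAN	miR-301	II
Sox9	TARGETSCAN	miR-494	II
Sox4	TARGETSCAN	miR-489	I
GATA-4	TARGETSCAN	miR-187	II
GATA-4	TARGETSCAN	miR-214	II
GATA-4	TARGETSCAN	miR-342	II
NeuroD1	TARGETSCAN	miR-17-5p	II
NeuroD1	TARGETSCAN	miR-18a	II
NeuroD1	TARGETSCAN	miR-92	II
NeuroD1	TARGETSCAN	miR-103	II
NeuroD1	TARGETSCAN	miR-494	II
Insm1	MIRBASE	miR-99b	II
Insm1	TARGETSCAN	miR-99b	II
Insm1	TARGETSCAN	miR-345	II
Insm1	TARGETSCAN	miR-494	II
Pax6	MIRBASE	miR-187	II
Pax6	TARGETSCAN	miR-130b	II
Pax6	TARGETSCAN	miR-301	II
Nkx2.2	MIRBASE	miR-182	II
MafB	TARGETSCAN	miR-181d	II
MafB	TARGETSCAN	miR-342	II
Foxa2	TARGETSCAN	miR-342	II
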