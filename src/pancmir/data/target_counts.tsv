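mirna_id	group	count_targetscan	count_mirbase	count_shared
miR-141	I	318	99	53
miR-7	I	463	152	43
miR-489	I	209	95	34
miR-98	I	105	55	12
miR-17-5p	II	433	121	65
miR-181d	II	349	114	55
miR-296	II	382	97	53
miR-214	II	513	92	48
miR-103	II	384	115	46
miR-181b	II	284	88	46
miR-125a	II	385	100	45
miR-484	II	455	82	40
miR-345	II	263	71	34
miR-301	II	215	69	28
miR-182	II	291	77	27
miR-18a	II	231	98	27
miR-218	II	248	89	27
miR-342	II	417	72	24
miR-130b	II	221	92	23
miR-135a	II	231	74	23
miR-323	II	274	67	22
miR-494	II	385	47	22
miR-382	II	193	58	21
miR-432	II	241	60	21
miR-135b	II	190	59	19
miR-25	II	151	46	17
miR-92	II	200	67	17
miR-21	II	106	56	15
miR-299-5p	II	162	64	15
miR-335	II	220	45	14
miR-187	II	60	71	12
miR-512-3p	II	120	19	12
miR-519d	II	139	28	11
miR-550	II	150	31	11
miR-96	II	124	47	11
miR-409-5p	II	85	55	10
miR-99b	II	32	76	7
miR-380-5p	II	200	30	6
miR-369-5p	II	19	54	2
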