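mirna_id	group
miR-7	I
miR-141	I
miR-98	I
miR-489	I
miR-92	II
miR-214	II
miR-484	II
miR-125a	II
miR-335	II
miR-218	II
miR-99b	II
miR-342	II
miR-382	II
miR-301	II
miR-432	II
miR-181b	II
miR-323	II
miR-103	II
miR-21	II
miR-130b	II
miR-135b	II
miR-182	II
miR-181d	II
miR-25	II
miR-17-5p	II
miR-296	II
miR-135a	II
miR-345	II
miR-299-5p	II
miR-18a	II
miR-369-5p	II
miR-519d	II
miR-494	II
miR-550	II
miR-187	II
miR-409-5p	II
miR-380-5p	II
miR-512-3p	II
miR-96	II
miR-26a	III
miR-19b	III
miR-126	III
miR-125b	III
miR-30c	III
miR-16	III
miR-24	III
miR-200c	III
miR-199a	III
miR-100	III
miR-99a	III
miR-26b	III
miR-594	III
miR-127	III
miR-20a	III
miR-130a	III
miR-30b	III
miR-30a-5p	III
miR-148a	III
miR-485-3p	III
miR-30d	III
miR-200a	III
miR-19a	III
miR-223	III
miR-106b	III
miR-331	III
miR-375	III
miR-197	III
miR-191	III
miR-93	III
miR-27a	III
miR-376a	III
miR-487b	III
miR-15b	III
miR-222	III
miR-410	III
miR-200b	III
miR-433	III
miR-142-3p	III
miR-186	III
miR-140	III
miR-152	III
miR-411	III
miR-365	III
miR-374	III
miR-324-3p	III
miR-27b	III
miR-10a	III
miR-320	III
miR-134	III
miR-429	III
miR-137	III
miR-149	III
miR-324-5p	III
miR-145	III
miR-151	III
miR-210	III
miR-204	III
miR-660	III
miR-328	III
miR-146b	III
miR-192	III
miR-221	III
let-7c	III
miR-30e-3p	III
miR-9	III
miR-30a-3p	III
miR-31	III
miR-28	III
miR-23b	III
let-7g	III
miR-148b	III
let-7a	III
miR-532	III
miR-379	III
miR-565	III
miR-20b	III
miR-32	III
miR-424	III
miR-425-5p	III
miR-361	III
miR-572	III
miR-30e-5p	III
miR-423	III
miR-10b	III
miR-183	III
miR-146a	III
miR-132	III
miR-195	III
miR-451	III
miR-485-5p	III
miR-199b	III
miR-23a	III
miR-194	III
miR-15a	III
miR-181c	III
let-7f	III
miR-340	III
miR-362	III
miR-22	III
miR-654	III
miR-330	III
miR-155	III
miR-501	III
hsa-let-7b	III
miR-142-5p	III
miR-615	III
miR-486	III
miR-143	III
miR-656	III
miR-95	III
miR-490	III
miR-101	III
miR-107	III
miR-193a	III
miR-383	III
miR-193b	III
miR-339	III
let-7e	III
let-7d	III
miR-372	III
miR-213	III
miR-491	III
miR-503	III
miR-224	III
miR-500	III
miR-493	III
miR-215	III
miR-425	III
miR-1	III
miR-502	III
miR-206	III
miR-650	III
miR-29c	III
miR-124a	III
miR-452	III
miR-133b	III
miR-139	III
miR-29a	III
miR-542-5p	III
miR-326	III
miR-488	III
miR-629	III
miR-369-3p	III
miR-496	III
miR-133a	III
miR-203	III
miR-378	III
miR-511	III
miR-520g	III
miR-17-3p	III
miR-190	III
miR-450	III
miR-518b	III
miR-659	III
miR-376b	III
miR-338	III
miR-504	III
miR-576	III
miR-545	III
miR-219	III
miR-518e	III
miR-642	III
miR-196b	III
miR-422a	III
miR-518c	III
miR-337	III
miR-189	III
miR-509	III
miR-299-3p	III
miR-381	III
miR-329	III
miR-518f	III
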