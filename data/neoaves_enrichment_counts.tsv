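family	common_name	n_reads	n_contigs	avg_contig_size	reads_in_contigs	n_uce_contigs	avg_uce_contig_size	reads_in_uce_contigs	n_multilocus_contigs	contigs_on_target_printed	reads_on_target_printed
Pittidae	Banded_Pitta	2723264	2369	386	914414	1572	457.4	719095	32	0.66	0.26
Viduidae	Pin-tailed_Whydah	1098154	1203	240	288210	959	244.2	234214	2	0.80	0.21
Psittacidae	Red-breasted_Parakeet	2745979	2312	421	974441	1487	508.1	752493	42	0.64	0.27
Falconidae	Collared_Forest_Falcon	1405847	742	309	229417	694	309.8	214967	8	0.94	0.15
Coliidae	Red-faced_Mousebird	2822685	2208	398	877590	1495	465.3	695586	43	0.68	0.25
Megalaimidae	Great_Barbet	2302531	1370	341	466552	1174	351.1	412208	10	0.86	0.18
Picidae	Yellow-bellied_Sapsucker	2693567	1952	388	757975	1542	416.5	642192	46	0.79	0.24
Phoeniculidae	Common_Scimitarbill	1829285	1742	382	665679	1425	411.1	585753	24	0.82	0.32
Momotidae	Blue-crowned_Motmot	2694269	2195	383	840829	1587	430.7	682265	45	0.72	0.25
Trogonidae	Masked_Trogon	2371840	1263	316	399423	1117	315.1	351958	13	0.88	0.15
Tytonidae	Barn_Owl	3543135	1833	338	620375	1464	360.9	528413	22	0.80	0.15
Accipitridae	Pearl_Kite	2605257	1588	525	833617	1351	557.6	753293	8	0.85	0.29
Cathartidae	Turkey_Vulture	2837787	2166	462	1001122	1551	528.9	820238	27	0.72	0.29
Phalacrocoracidae	Great_Cormorant	4892448	1601	521	834275	1384	554.1	766906	10	0.86	0.16
Scopidae	Hamerkop	3322061	2024	533	1079622	1580	598.1	944999	46	0.78	0.28
Balaenicipitidae	Shoebill	1906136	1784	420	749552	1485	448.9	666057	19	0.83	0.35
Spheniscidae	Little_Penguin	3009607	2418	434	1049164	1681	507.5	852753	42	0.70	0.28
Hydrobatidae	Wilsons_Storm_Petrel	2519648	1930	488	942397	1574	535.6	842403	18	0.82	0.33
Gaviidae	Common_Loon	2947546	2132	386	821803	1492	431.7	644027	17	0.70	0.22
Nyctibiidae	Great_Potoo	4224329	2060	377	776650	1474	421.0	620400	78	0.72	0.15
Trochilidae	Sparkling_Violetear	2496109	1881	384	723418	1435	425.8	608046	25	0.76	0.24
Phaethontidae	Red-tailed_Tropicbird	2956951	1875	423	792485	1450	460.9	668317	36	0.77	0.23
Eurypygidae	Sunbittern	3181048	1988	416	827124	1585	450.2	713511	16	0.80	0.22
Opisthocomidae	Hoatzin	1848363	1427	307	438153	1257	309.4	388853	8	0.88	0.21
Otididae	Kori_Bustard	2058864	2000	389	777365	1489	436.0	649136	54	0.74	0.32
Musophagidae	Red-crested_Turaco	3031838	2134	402	858470	1571	447.8	702976	37	0.74	0.23
Columbidae	Pink-necked_Green_Pigeon	1949899	1771	370	655866	1337	409.7	547817	47	0.75	0.28
Pteroclididae	Chestnut-bellied_Sandgrouse	2167890	1303	341	444614	1130	351.0	396601	30	0.87	0.18
Phoenicopteridae	Chilean_Flamingo	2826576	1878	371	696317	1486	400.5	595072	56	0.79	0.21
Podicipedidae	Horned_Grebe	2929983	1502	391	587752	1296	402.1	521175	2	0.86	0.18
Charadriidae	Diademed_Sandpiper-plover	2488988	1892	355	671797	1518	381.9	579714	49	0.80	0.23
Psophiidae	Grey-winged_Trumpeter	2224282	2010	368	739996	1550	401.9	622967	26	0.77	0.28
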