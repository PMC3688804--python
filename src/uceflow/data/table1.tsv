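taxon	trimmed_reads	contigs_assembled	reads_in_contigs	uce_contigs	reads_in_uce_contigs	avg_size	avg_coverage
Umbra limi	2727071	1109	740079	409	564715	508.8	267.4
Diaphus theta	2626413	584	688635	401	604295	502.4	299.1
Antennarius striatus	3724320	474	2462193	418	2310186	649.7	850.2
Megalops sp.	2771805	786	650577	247	231314	485.4	191.5
Astyanax fasciatus	2731668	543	1444767	355	1211903	526.2	657.2
Acanthurus japonicus	2017174	613	1242932	454	1125871	600.8	405.9
Amia calva	2619643	562	1608614	366	1368091	578.9	646
Lampris guttatus	2472439	486	1350852	418	1237650	568.7	520.2
Acipenser fulvescens	3083152	577	1129829	167	467414	426.9	665.4
Anchoa compressa	2617717	533	783323	287	625862	448.6	479.2
Danio rerio	2777132	518	1367065	382	1166020	463.4	657.1
Polypterus senegalus	3206418	576	873104	294	726100	557.6	440
Pantodon buchholzi	3329691	466	2058929	272	1399286	550.4	930.5
Strophidon sathete	3159269	1007	448390	277	246758	510.6	172.9
Osteoglossum bicirrhosum	2735138	643	1565346	276	813175	467	623.9
Salvelinus fontinalis	2466696	1118	688684	166	161214	408.7	234.8
Taenianotus triacanthus	3245453	712	1423244	447	1252564	652.5	431.4
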