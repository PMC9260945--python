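# Published global reactivity descriptors (eV) for the library 4a-4o:
# gap, chemical hardness, chemical potential, electrophilicity as printed.
compound_id	e_homo_ev	e_lumo_ev	gap_ev	hardness_ev	chemical_potential_ev	electrophilicity_ev
4a	-5.3878	-1.4150	3.9728	1.9864	-3.4014	2.9122
4b	-5.5511	-1.5238	4.0273	2.0137	-3.5375	3.1072
4c	-5.2790	-1.3878	3.8912	1.9456	-3.3334	2.8556
4d	-5.4151	-1.6055	3.8096	1.9048	-3.5103	3.2345
4e	-5.5239	-1.5238	4.0001	2.0001	-3.5239	3.1043
4f	-5.8232	-2.4218	3.4014	1.7007	-4.1225	4.9965
4g	-5.7144	-2.2858	3.4286	1.7143	-4.0001	4.6669
4h	-5.2790	-1.3606	3.9184	1.9592	-3.3198	2.8126
4i	-5.4151	-1.4966	3.9185	1.9593	-3.4559	3.0478
4j	-5.1702	-1.3606	3.8096	1.9048	-3.2654	2.7989
4k	-5.6055	-2.2585	3.3470	1.6735	-3.9320	4.6192
4l	-5.1702	-1.2517	3.9185	1.9593	-3.2110	2.6312
4m	-5.4151	-1.4966	3.9185	1.9593	-3.4559	3.0478
4n	-5.1429	-1.3334	3.8095	1.9048	-3.2382	2.7525
4o	-5.6872	-2.3674	3.3198	1.6599	-4.0273	4.8856
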