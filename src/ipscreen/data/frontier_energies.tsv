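# Frontier orbital energies (eV) for the library 4a-4o, as published.
compound_id	e_homo_ev	e_lumo_ev
4a	-5.3878	-1.4150
4b	-5.5511	-1.5238
4c	-5.2790	-1.3878
4d	-5.4151	-1.6055
4e	-5.5239	-1.5238
4f	-5.8232	-2.4218
4g	-5.7144	-2.2858
4h	-5.2790	-1.3606
4i	-5.4151	-1.4966
4j	-5.1702	-1.3606
4k	-5.6055	-2.2585
4l	-5.1702	-1.2517
4m	-5.4151	-1.4966
4n	-5.1429	-1.3334
4o	-5.6872	-2.3674
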