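# Imidazo[1,2-a]pyridin-3-yl library 4a-4o: scaffold SMILES reconstructed from
# the R1 (aminopyridine) / R2 (aryl) substituent grammar; nitro written
# hypervalent so the Ertl nitro fragment applies.
id	smiles	r1	r2
4a	OC1=C(C(=O)CC(C)(C)C1)c1n2ccccc2nc1-c1ccccc1	H	H
4b	OC1=C(C(=O)CC(C)(C)C1)c1n2ccccc2nc1-c1ccc(Cl)cc1	H	4-Cl
4c	OC1=C(C(=O)CC(C)(C)C1)c1n2ccccc2nc1-c1ccccc1O	H	2-OH
4d	OC1=C(C(=O)CC(C)(C)C1)c1n2ccccc2nc1-c1ccc(OC)cc1	H	4-OMe
4e	OC1=C(C(=O)CC(C)(C)C1)c1n2ccccc2nc1-c1ccc(Br)cc1	H	4-Br
4f	OC1=C(C(=O)CC(C)(C)C1)c1n2ccccc2nc1-c1cccc(c1)N(=O)=O	H	3-NO2
4g	OC1=C(C(=O)CC(C)(C)C1)c1n2ccccc2nc1-c1ccc(cc1)N(=O)=O	H	4-NO2
4h	OC1=C(C(=O)CC(C)(C)C1)c1n2cc(C)ccc2nc1-c1ccccc1	4-CH3	H
4i	OC1=C(C(=O)CC(C)(C)C1)c1n2cc(C)ccc2nc1-c1ccc(Br)cc1	4-CH3	4-Br
4j	OC1=C(C(=O)CC(C)(C)C1)c1n2cc(C)ccc2nc1-c1ccc(O)cc1	4-CH3	4-OH
4k	OC1=C(C(=O)CC(C)(C)C1)c1n2cc(C)ccc2nc1-c1cccc(c1)N(=O)=O	4-CH3	3-NO2
4l	OC1=C(C(=O)CC(C)(C)C1)c1n2cc(C)ccc2nc1-c1ccccc1O	4-CH3	2-OH
4m	OC1=C(C(=O)CC(C)(C)C1)c1n2cc(C)ccc2nc1-c1ccc(Cl)cc1	4-CH3	4-Cl
4n	OC1=C(C(=O)CC(C)(C)C1)c1n2cc(C)ccc2nc1-c1ccc(OC)cc1	4-CH3	4-OMe
4o	OC1=C(C(=O)CC(C)(C)C1)c1n2cc(C)ccc2nc1-c1ccc(cc1)N(=O)=O	4-CH3	4-NO2
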