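# Hydrogen-bond contact records for the library 4a-4o and olprinone with
# phosphodiesterase 3B (bond energies kJ/mol, lengths A).
ligand_id,target_id,residue,ligand_atom,bond_energy_kj_mol,bond_length_A
4a,PDE3B,Ser 857 (O),N (12),-2.50000,3.04544
4a,PDE3B,Asn 860 (O),O (24),-0.12746,3.57007
4a,PDE3B,Asn 860 (N),O (24),-1.87070,2.82732
4a,PDE3B,Ser 864 (O),O (24),-2.50000,2.79733
4b,PDE3B,Ser 857 (O),N (12),-2.50000,2.79195
4b,PDE3B,Asn 860 (N),O (23),-0.84588,2.79866
4b,PDE3B,His 873 (N),O (24),-0.76499,3.44700
4c,PDE3B,Ser 857 (O),N (12),-2.16410,3.16718
4c,PDE3B,Leu 872 (O),O (25),-2.50000,2.73473
4d,PDE3B,Ser 857 (O),N (12),-2.50000,2.80191
4d,PDE3B,Asn 860 (N),O (23),-0.84081,2.71526
4d,PDE3B,His 873 (N),O (24),-1.18401,3.36320
4e,PDE3B,Ser 857 (O),N (12),-2.50000,2.80803
4e,PDE3B,Asn 860 (N),O (23),-0.85524,2.76409
4e,PDE3B,His 873 (N),O (24),-0.79468,3.44106
4f,PDE3B,Ser 857 (O),N (12),-2.50000,3.04756
4f,PDE3B,Ser 864 (O),N (25),-1.84526,3.23095
4f,PDE3B,Ser 864 (O),O (27),-2.50000,2.60137
4f,PDE3B,His 873 (N),O (24),-2.50000,2.92871
4g,PDE3B,Ser 857 (O),N (12),-2.40937,3.11813
4g,PDE3B,Ser 864 (O),N (25),-2.42875,3.11425
4g,PDE3B,Asn 860 (N),O (26),-1.15490,3.33927
4g,PDE3B,Ser 864 (O),O (27),-2.49723,2.59967
4h,PDE3B,Ser 857 (O),N (12),-2.50000,2.86090
4h,PDE3B,Asn 860 (N),O (23),-0.87540,2.75165
4h,PDE3B,His 873 (N),O (24),-0.42234,3.51553
4i,PDE3B,Ser 857 (O),N (12),-2.49607,3.10079
4i,PDE3B,Asn 860 (N),O (23),-0.98413,2.66454
4j,PDE3B,Ser 857 (O),N (12),-2.50000,3.07232
4j,PDE3B,Asn 860 (N),O (23),-1.01043,2.65725
4j,PDE3B,Leu 872 (O),O (26),-2.50000,2.75209
4k,PDE3B,Ser 857 (O),N (12),-2.50000,2.64745
4k,PDE3B,Asn 860 (N),O (23),-0.69619,2.81216
4k,PDE3B,Ser 864 (O),N (26),-2.50000,2.71435
4k,PDE3B,Asn 860 (N),O (28),-2.48162,3.10368
4k,PDE3B,Ser 864 (O),O (28),-0.03093,2.31362
4k,PDE3B,His 873 (N),O (24),-1.08396,3.38321
4l,PDE3B,Ser 857 (O),N (12),-2.50000,2.89671
4l,PDE3B,Asn 860 (N),O (23),-0.86219,2.61278
4l,PDE3B,Ser 857 (O),O (26),-1.98567,3.20287
4l,PDE3B,Ser 857 (O),O (26),-2.50000,2.61160
4l,PDE3B,His 873 (N),O (24),-0.91767,3.41647
4l,PDE3B,His 873 (N),O (26),-0.81479,3.43704
4m,PDE3B,Ser 857 (O),N (12),-2.50000,3.09672
4m,PDE3B,Asn 860 (N),O (23),-0.97299,2.64190
4n,PDE3B,Asn 860 (N),N (11),-0.02900,3.52202
4n,PDE3B,Ser 857 (O),N (12),-2.50000,3.01701
4n,PDE3B,Asn 860 (N),O (24),-0.27708,2.92932
4n,PDE3B,Tyr 844 (O),O (26),-2.49089,2.59891
4n,PDE3B,His 853 (N),O (26),-2.50000,3.06206
4o,PDE3B,Asn 860 (N),N (11),-0.08751,3.51567
4o,PDE3B,Ser 857 (O),N (12),-1.47668,3.30466
4o,PDE3B,Asn 860 (N),O (24),-0.14193,2.46943
4o,PDE3B,Tyr 844 (O),N (26),-2.50000,2.60095
4o,PDE3B,His 853 (N),N (26),-2.50000,3.02081
4o,PDE3B,Tyr 844 (O),O (27),-1.84732,2.08756
olprinone,PDE3B,Ser 857 (O),N (8),-1.53755,3.29249
olprinone,PDE3B,Ser 864 (O),O (15),-2.50000,3.08748
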