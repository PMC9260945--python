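# Hydrogen-bond contact records for the library 4a-4o and minodronic acid
# with farnesyl diphosphate synthase (bond energies kJ/mol, lengths A).
ligand_id,target_id,residue,ligand_atom,bond_energy_kj_mol,bond_length_A
4a,FDPS,Ser 205 (O),N (11),-1.61890,3.27622
4a,FDPS,Ser 205 (O),N (12),-2.50000,2.61902
4a,FDPS,Arg 60 (N),O (24),-0.00775,2.29911
4b,FDPS,Tyr 58 (N),O (23),-0.01189,3.57803
4b,FDPS,Asn 59 (N),O (23),-0.73913,2.59207
4b,FDPS,Arg 60 (N),O (23),-2.50000,2.82512
4c,FDPS,Tyr 58 (N),O (23),-0.10649,3.44088
4c,FDPS,Asn 59 (N),O (23),-1.08913,2.58761
4c,FDPS,Arg 60 (N),O (23),-2.50000,3.09408
4c,FDPS,Ser 205 (O),O (25),-2.04184,2.54502
4d,FDPS,Tyr 58 (N),O (23),-0.09476,3.44893
4d,FDPS,Asn 59 (N),O (23),-1.06219,2.56740
4d,FDPS,Arg 60 (N),O (23),-2.49363,3.10127
4e,FDPS,Tyr 58 (N),O (23),-0.02610,3.54831
4e,FDPS,Asn 59 (N),O (23),-0.65880,2.55617
4e,FDPS,Arg 60 (N),O (23),-2.50000,2.82583
4f,FDPS,Ser 205 (O),N (12),-2.50000,3.00863
4f,FDPS,Arg 60 (N),O (24),-0.20808,3.15632
4f,FDPS,Arg 60 (N),O (24),-1.35251,2.14446
4f,FDPS,Asn 59 (N),N (25),-0.25464,3.54907
4f,FDPS,Thr 63 (O),N (25),-2.41718,3.11656
4f,FDPS,Thr 63 (O),O (26),-2.50000,2.60213
4f,FDPS,Asn 59 (N),O (27),-2.50000,2.60025
4g,FDPS,Asn 59 (N),O (23),-0.57469,2.64989
4g,FDPS,Arg 60 (N),O (23),-2.50000,2.61028
4g,FDPS,Asn 59 (N),N (25),-0.09783,3.58043
4g,FDPS,Thr 63 (O),N (25),-1.10088,3.37982
4g,FDPS,Asn 59 (N),O (26),-2.50000,2.60122
4g,FDPS,Thr 63 (O),O (27),-2.50000,2.80632
4h,FDPS,Arg 60 (N),N (12),-1.49341,3.04388
4h,FDPS,Arg 60 (N),O (24),-0.84816,3.12660
4h,FDPS,Arg 60 (N),O (24),-2.02485,2.06714
4h,FDPS,Tyr 204 (O),O (24),-1.20691,3.35862
4h,FDPS,Ser 205 (O),O (24),-0.17050,2.32046
4i,FDPS,Ser 205 (O),N (12),-2.50000,2.88372
4i,FDPS,Arg 60 (N),O (24),-2.22715,3.10029
4i,FDPS,Glu 93 (O),O (24),-1.94256,3.21149
4j,FDPS,Tyr 58 (N),O (23),-0.05245,3.51506
4j,FDPS,Asn 59 (N),O (23),-0.99386,2.59110
4j,FDPS,Arg 60 (N),O (23),-2.50000,2.99640
4j,FDPS,Ser 205 (O),O (26),-2.39738,2.58769
4k,FDPS,Arg 60 (N),N (12),-1.36329,2.79244
4k,FDPS,Arg 60 (N),O (23),-1.81084,2.55609
4k,FDPS,Tyr 204 (O),O (23),-0.26226,3.54755
4k,FDPS,Ser 205 (O),O (23),-2.49869,2.59998
4k,FDPS,Arg 60 (N),O (27),-2.41387,3.09897
4k,FDPS,Arg 60 (N),O (27),-2.34329,3.12369
4k,FDPS,Arg 113 (N),O (28),-1.17171,2.90942
4k,FDPS,Arg 113 (N),O (28),-0.99612,3.11867
4l,FDPS,Arg 60 (N),N (12),-1.53196,3.08287
4l,FDPS,Arg 60 (N),O (24),-0.85461,3.12642
4l,FDPS,Arg 60 (N),O (24),-1.99573,2.07049
4l,FDPS,Tyr 204 (O),O (24),-1.22651,3.35470
4l,FDPS,Ser 205 (O),O (24),-0.11522,2.31383
4l,FDPS,Tyr 58 (N),O (26),-0.20459,3.10284
4l,FDPS,Asn 59 (N),O (26),-2.48350,2.75736
4m,FDPS,Tyr 58 (N),O (23),-0.01605,3.57054
4m,FDPS,Asn 59 (N),O (23),-0.92761,2.57293
4m,FDPS,Arg 60 (N),O (23),-2.50000,2.94743
4n,FDPS,Tyr 58 (N),O (23),-0.08319,3.46818
4n,FDPS,Asn 59 (N),O (23),-1.07656,2.57721
4n,FDPS,Arg 60 (N),O (23),-2.50000,3.08395
4o,FDPS,Arg 60 (N),N (12),-2.48607,3.08471
4o,FDPS,Arg 113 (N),O (23),-1.80969,2.61959
4o,FDPS,Tyr 58 (N),N (26),-1.66976,3.21718
4o,FDPS,Asn 59 (N),O (27),-2.05854,3.09542
4o,FDPS,Tyr 58 (N),O (28),-2.49951,2.71332
minodronic acid,FDPS,Glu 93 (O),O (11),-2.50000,2.62058
minodronic acid,FDPS,Arg 60 (N),O (15),-2.20851,3.05595
minodronic acid,FDPS,Arg 60 (N),O (15),-2.22001,3.09973
minodronic acid,FDPS,Glu 93 (O),O (16),-2.50000,2.64215
minodronic acid,FDPS,Arg 113 (N),O (16),-0.35967,3.26586
minodronic acid,FDPS,Tyr 58 (N),O (17),-2.40243,2.62664
minodronic acid,FDPS,Glu 93 (O),O (17),-2.50000,2.70066
minodronic acid,FDPS,Arg 60 (N),O (15),-2.36085,3.09912
minodronic acid,FDPS,Asn 59 (N),O (19),-2.50000,2.60019
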