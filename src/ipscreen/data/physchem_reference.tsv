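# Published physicochemical / rule-of-five descriptor set for the library
# 4a-4o and the reference standards (MW g/mol; TPSA A^2; logP octanol/water;
# nlv = number of Lipinski violations as published).
compound_id	mw	n_hba	n_hbd	tpsa	logp	nlv
4a	332.40	3	1	54.60	3.56	0
4b	366.84	3	1	54.60	4.12	0
4c	348.40	4	2	74.83	3.18	0
4d	362.42	4	1	63.83	3.59	0
4e	411.29	3	1	54.60	4.19	0
4f	377.39	5	1	100.42	2.85	0
4g	377.39	5	1	100.42	2.84	0
4h	346.42	3	1	54.60	3.89	0
4i	425.32	3	1	54.60	4.54	0
4j	362.42	4	2	74.83	3.49	0
4k	391.42	5	1	100.42	3.20	0
4l	362.42	4	2	74.83	3.45	0
4m	380.87	3	1	54.60	4.45	0
4n	376.45	4	1	63.83	3.91	0
4o	391.42	5	1	100.42	3.21	0
alpidem	404.33	2	0	37.61	4.89	0
ciprofloxacin	331.34	5	2	74.57	1.10	0
GSK812397	402.35	7	1	60.14	2.44	0
minodronic acid	680.79	8	5	172.21	-1.74	0
miroprofen	266.29	3	1	54.60	2.64	0
necopidem	363.50	2	0	37.61	4.40	0
olprinone	250.26	3	1	73.95	1.67	0
saripidem	341.83	2	0	37.61	3.66	0
zolimidine	272.32	3	0	59.82	2.25	0
zolpidem	307.39	2	0	37.61	3.13	0
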