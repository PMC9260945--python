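# Published per-atom local reactivity table for compound 4o (NBO charges at
# the N and N+1 electron states plus printed condensed Fukui indices).
# Imported verbatim; the printed f columns are not recomputed from the q
# columns (they are not mutually consistent in the published table).
atom_label	element	q_n	q_nplus1	f_plus	f_minus	f_zero
C1	C	-0.151310	-0.38542	-0.401360	0.250047	0.007970
C2	C	-0.092970	0.42033	0.249521	-0.342490	0.085405
C3	C	0.238183	-0.47370	-0.483440	0.721625	0.004871
C4	C	0.184695	-0.22889	-0.304330	0.489020	0.037720
C5	C	-0.362620	0.29922	0.587872	-0.950490	-0.144325
C6	C	0.174867	-0.12933	-0.309850	0.484712	0.090258
C7	C	0.312993	0.10023	0.122315	0.190678	-0.011042
C8	C	0.018006	0.23488	0.088316	-0.070310	0.073283
C9	C	-0.081770	0.11073	0.221697	-0.303470	-0.055486
C10	C	-0.054300	0.09544	-0.083020	0.028717	0.089229
C11	C	0.218577	-0.13781	-0.092950	0.311523	-0.022431
N12	N	-0.355590	0.29693	0.247717	-0.603310	0.024607
N13	N	-0.378090	0.08790	0.007784	-0.385870	0.040059
C14	C	0.061015	-0.355810	-0.393740	0.454753	0.018966
C15	C	0.104763	0.091094	0.097453	0.007310	-0.003180
C16	C	-0.163560	0.659550	0.587435	-0.750990	0.036058
C17	C	0.119294	-0.270240	-0.435790	0.555082	0.082774
C18	C	0.033791	0.474118	0.331978	-0.298190	0.071070
C19	C	0.210717	-0.463470	-0.462950	0.673667	-0.000261
C20	C	-0.217070	-0.798400	-0.934870	0.717799	0.068236
C21	C	0.364037	-0.545010	-0.431450	0.795488	-0.056778
C22	C	0.128279	0.214642	0.058900	0.069379	0.077871
C23	C	0.138569	0.009307	-0.145230	0.283802	0.077270
O24	O	-0.344970	-0.018290	-0.188560	-0.156420	0.085135
O25	O	0.201408	1.660380	1.485765	-1.284360	0.087308
C26	C	0.114567	0.167997	0.018904	0.095663	0.074547
N27	N	0.123946	-0.227000	-0.256400	0.380350	0.014704
O28	O	-0.229870	0.098736	-0.026610	-0.203250	0.062675
O29	O	-0.315590	0.011858	-0.155120	-0.160470	0.083489
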