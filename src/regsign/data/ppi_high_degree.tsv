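node	degree	betweenness	closeness	fold_change	p_adj
Ywhae	2918	0.81	0.62
Pgls	593	0.047	0.45
Ywhaz	495	0.047	0.46
Hsd3b7	462	0.013	0.35
Ywhah	285	0.058	0.44
Fos	213	0.046	0.35	-1.5	0.019
Parp1	211	0.050	0.36	1.2	0.094
Nr3c1	207	0.048	0.35	1.3	0.95
IDB-74	146	0.043	0.33
Fadd	109	0.032	0.33	1.3	0.013
Cenpc1	99	0.022	0.41
Irs1	81	0.020	0.43
Rad51	81	0.020	0.33
Foxo3	80	0.026	0.43	1.0	0.28
Gfi1	80	0.018	0.33	-1.3	0.0058
Nphp1	80	0.016	0.33	-1.2	0.0726
Ubc	78	0.038	0.37
Foxo1	76	0.013	0.35	1.3	1
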