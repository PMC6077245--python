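lncRNA_gene	lncRNA_transcript	position	hp_fpkm	lp_fpkm	p_value	q_value
XLOC_004729	TCONS_0023641	1:125572871-125585794	0	0.927357	5.00E-05	0.00328028
XLOC_013834	TCONS_0089292	1:56905028-56948667	0	1.19118	0.0017	0.0457879
XLOC_1186672	TCONS_1844622	6:72896473-72900508	0	3.07993	0.00045	0.0181805
XLOC_1284424	TCONS_2040856	8:65415622-65417104	0	0.903789	0.00065	0.0240837
XLOC_144456	TCONS_0207836	10:102838283-102839042	0	1.52439	5.00E-05	0.00328028
XLOC_1560985	TCONS_2392159	20:51729259-51767218	0	1.29975	5.00E-05	0.00328028
XLOC_2273208	TCONS_3400346	3:87803076-87803851	0	0.820661	5.00E-05	0.00328028
XLOC_2938516	TCONS_4397837	7:36583792-36603493	0	1.40913	5.00E-05	0.00328028
XLOC_593004	TCONS_1139318	12:75887263-75896281	0	0.829202	5.00E-05	0.00328028
XLOC_890495	TCONS_1424422	28:44935176-44936429	0	0.849668	5.00E-05	0.00328028
XLOC_051681	TCONS_0229895	1:83581354-83582143	0.870136	0	5.00E-05	0.00328028
XLOC_1261332	TCONS_2499784	19:39080345-39080701	3.5376	0	0.001	0.0327277
XLOC_157700	TCONS_0265438	11:43723923-43734354	2.41705	0	0.00135	0.0392433
XLOC_2552245	TCONS_3954401	5:31711309-31754936	1.17274	0	5.00E-05	0.00328028
XLOC_2928338	TCONS_4440543	7:21632727-21642878	2.14752	0	0.00135	0.0392433
XLOC_3202784	TCONS_6404733	9:39279279-39285358	1.74985	0	0.00135	0.0392433
XLOC_3294518	TCONS_5106036	X:4233697-4243280	0.814726	0	0.00085	0.0296505
XLOC_547975	TCONS_1098704	12:1470993-1491509	4.52107	0	0.0018	0.0474099
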