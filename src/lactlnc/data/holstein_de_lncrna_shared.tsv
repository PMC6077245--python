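lncRNA_gene	lncRNA_transcript	position	hp_fpkm	lp_fpkm	log2fc	p_value	q_value
XLOC_582693	TCONS_0918942	2:115673519-115682184	3.31278	1.02906	-1.68671	5.00E-05	0.00328028
XLOC_059976	TCONS_0458010	5:32243816-32270339	2.05417	0.690516	-1.57281	0.0003	0.0133664
XLOC_929036	TCONS_1690898	15:65891595-65896543	1.0145	0.346711	-1.54897	0.00145	0.0416424
XLOC_2280878	TCONS_4547736	3:56909914-56937217	2.39104	0.832575	-1.52199	5.00E-05	0.00328028
XLOC_3326303	TCONS_6686797	GJ060358.1:32-6493	2.15126	0.767271	-1.48737	0.0001	0.00558672
XLOC_1553010	TCONS_3078081	20:12598342-12605288	1.48105	0.665365	-1.1544	0.0013	0.038494
XLOC_292033	TCONS_0432200	10:26697899-26702683	2.79144	1.39491	-1.00084	0.0007	0.0256703
XLOC_240033	TCONS_0542901	10:48376509-48648893	68.8414	35.3762	-0.960497	0.00105	0.0336706
XLOC_112491	TCONS_0385499	1:19929165-20182412	5.13451	8.07422	0.653097	0.00095	0.0316711
XLOC_1815349	TCONS_3601672	23:17507725-17522447	5.00749	9.53541	0.929207	0.001	0.0327277
XLOC_2500996	TCONS_4893811	4:33260787-33262913	1.35118	3.31447	1.29456	0.0004	0.0168259
XLOC_2427074	TCONS_4920751	4:36158377-36159816	1.25597	6.38418	2.3457	5.00E-05	0.00328028
XLOC_1243232	TCONS_1975869, TCONS_1991976	7:38449464-38502848	0.408342	2.81355	2.78454	0.0002	0.00966351
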