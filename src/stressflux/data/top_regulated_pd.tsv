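gene	name	fold_change_signed	error	direction
b1743	spy	6447	2830	up
b1970	hiuH	1465	986	up
b3686	ibpB	565	94	up
b4002	zraP	357	45	up
b4484	cpxP	330	92	up
b4062	soxS	240	28	up
b2074	mdtA	188	47	up
b4140	fxsA	163	35	up
b3263	yhdU	160	148	up
b1742	ves	151	88	up
b2162	rihB	133	17	up
b3501	arsR	132	20	up
b1972	yedZ	112	15	up
b0484	copA	101	10	up
b3828	metR	100	4	up
b1971	yedY	96	8	up
b3708	tnaA	94	3	up
b4670	yjeV	81	63	up
b3502	arsB	76	8	up
b3687	ibpA	70	7	up
b2725	hycA	-520	151	down
b1038	csgF	-338	60	down
b3215	yhcA	-197	32	down
b0336	codB	-130	23	down
b2145	yeiS	-130	103	down
b2269	elaD	-119	13	down
b4665	ibsC	-117	28	down
b2345	yfdF	-117	19	down
b4128	ghoS	-110	12	down
b1520	yneE	-109	27	down
b0945	pyrD	-106	21	down
b3622	waaL	-85	13	down
b0991	ymcE	-80	64	down
b2352	gtrS	-70	16	down
b2497	uraA	-59	4	down
b2669	stpA	-50	14	down
b0564	appY	-49	23	down
b4345	mcrC	-44	5	down
b3508	yhiD	-41	16	down
b1018	efeO	-41	7	down
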