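condition	up	down	ambiguous	no_flux
BENZ	122	558	12
XID	72	575	14
PHE	80	590	9
GLUTA	48	593	9
H2O2	103	555	11
ETOH	84	580	13
ISOP	79	573	15
PERA	76	563	10
POV	71	585	8
SOD	55	590	11
PAL	17	120	1485	1090
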