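exposure	rsid	effect_allele	eaf	beta	pval
homocysteine	rs1801133	A	0.34	0.1583	4.34E-104
homocysteine	rs2275565	T	0.21	-0.0542	1.96E-10
homocysteine	rs7422339	A	0.33	0.0864	4.58E-27
homocysteine	rs9369898	A	0.62	0.0449	2.17E-10
homocysteine	rs7130284	T	0.07	-0.1242	1.88E-20
homocysteine	rs154657	A	0.47	0.0963	1.74E-43
homocysteine	rs234709	T	0.45	-0.0718	3.90E-24
homocysteine	rs4660306	T	0.33	0.0435	2.33E-09
homocysteine	rs548987	C	0.13	0.0597	1.12E-08
homocysteine	rs42648	A	0.4	-0.0395	1.97E-08
homocysteine	rs1801222	A	0.34	0.0453	8.43E-10
homocysteine	rs2251468	A	0.65	-0.0512	1.28E-12
homocysteine	rs838133	A	0.45	0.0422	7.48E-09
homocysteine	rs12134663	A	0.8	-0.101	2.54E-21
homocysteine	rs12780845	A	0.65	0.0529	7.80E-10
homocysteine	rs957140	A	0.45	-0.045	2.43E-10
homocysteine	rs12921383	T	0.87	-0.09	8.22E-11
homocysteine	rs2851391	T	0.47	0.056	1.70E-12
folate	rs1801133	G	0.67	0.096	9.50E-53
folate	rs17421511	G	0.83	0.098	1.80E-15
folate	rs652197	C	0.18	0.069	1.20E-14
cobalamin	rs602662	A	0.6	0.16	2.40E-139
cobalamin	rs34324219	C	0.88	0.21	1.10E-111
cobalamin	rs34528912	T	0.04	0.17	2.10E-15
cobalamin	rs117456053	G	0.98	0.16	1.90E-09
cobalamin	rs1801222	G	0.59	0.11	3.30E-75
cobalamin	rs56077122	A	0.33	0.087	4.80E-21
cobalamin	rs2336573	T	0.03	0.32	8.40E-59
cobalamin	rs1131603	C	0.055	0.19	4.90E-49
cobalamin	rs5753231	C	0.79	0.064	7.50E-10
cobalamin	rs41281112	C	0.95	0.17	8.90E-35
cobalamin	rs1141321	C	0.63	0.061	3.60E-26
cobalamin	rs3742801	T	0.29	0.045	1.70E-13
cobalamin	rs2270655	G	0.94	0.066	2.20E-13
cobalamin	rs12272669	A	0.0022	0.51	3.00E-09
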