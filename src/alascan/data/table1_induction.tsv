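strain	position	wt_residue	group	mean_uninduced	sd_uninduced	mean_induced	sd_induced	fold_printed	ms_verified
RbsB	0	-	wild_type	2851	544	23663	2958	8.30	1
L6A	6	L	non_inducible	2293	107	1495	34	0.65	1
T10A	10	T	non_inducible	2604	629	1884	454	0.72	1
D215A	215	D	non_inducible	3696	40	2816	25	0.76	1
D89A	89	D	non_inducible	2416	503	1932	295	0.80	1
K29A	29	K	non_inducible	2039	49	1736	38	0.85	1
N41A	41	N	non_inducible	2823	409	2459	84	0.87	1
N190A	190	N	non_inducible	2396	39	2179	92	0.91	1
V186A	186	V	non_inducible	992	133	940	119	0.95	1
G196A	196	G	non_inducible	990	155	950	103	0.96	1
L88A	88	L	non_inducible	1123	55	1103	28	0.98	1
L195A	195	L	poorly_inducible	1005	37	1594	51	1.59	1
V106A	106	V	poorly_inducible	1107	262	1761	262	1.59	1
D264A	264	D	poorly_inducible	3059	161	5726	456	1.87	1
L34A	34	L	poorly_inducible	2207	229	4432	115	2.01	1
G31A	31	G	poorly_inducible	2537	343	5761	165	2.27	1
P262A	262	P	poorly_inducible	1906	418	6004	1649	3.15	1
D104A	104	D	poorly_inducible	1235	34	4068	596	3.29	0
R141A	141	R	poorly_inducible	2123	494	7006	1474	3.30	1
I86A	86	I	poorly_inducible	2246	260	7873	2393	3.51	1
G144A	144	G	poorly_inducible	2378	89	8926	348	3.75	1
I111A	111	I	poorly_inducible	1963	170	8728	590	4.45	1
P237A	237	P	poorly_inducible	2923	244	10267	2976	3.51	1
I233A	233	I	poorly_inducible	3166	217	10555	2856	3.33	1
N105A	105	N	semi_constitutive	8344	171	35539	219	4.26	1
S103A	103	S	semi_constitutive	7167	167	33101	1963	4.62	0
E255A	255	E	semi_constitutive	6824	324	31441	595	4.61	0
I132A	132	I	semi_constitutive	5741	731	24383	145	4.25	1
Q80A	80	Q	semi_constitutive	5324	203	32831	1549	6.17	0
I63A	63	I	semi_constitutive	4945	134	20414	660	4.13	1
F154A	154	F	semi_constitutive	4460	102	23688	340	5.31	0
I240A	240	I	semi_constitutive	4314	395	23434	3754	5.43	0
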