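strain	position	group	induced_fluorescence	ms_expression	ms_bracketed	ms_low_bold	norm_fluorescence	norm_abundance
RbsB	0	wild_type	23663	47	0	0	1	1
L6A	6	signaling_and_abundance	1495	23	1	1	0.063	NC
T10A	10	signaling_and_abundance	1884	8	1	1	0.080	0.168
K29A	29	signaling_and_abundance	1736	10	0	1	0.073	0.212
G31A	31	signaling_and_abundance	5761	17	0	1	0.243	0.367
L34A	34	signaling_and_abundance	4432	17	0	1	0.187	0.367
N41A	41	signaling_and_abundance	2459	7	0	1	0.104	0.150
L88A	88	signaling_and_abundance	1103	15	1	1	0.047	0.323
L195A	195	signaling_and_abundance	1594	24	1	1	0.067	0.512
I63A	63	abundance	20414	21	0	1	0.863	0.445
I86A	86	abundance	7873	15	0	1	0.333	0.319
N190A	190	abundance	2179	4	0	1	0.092	0.075
I233A	233	abundance	10555	17	0	1	0.446	0.365
V106A	106	signaling	1761	111	1	0	0.074	2.36
P262A	262	signaling	6004	60	0	0	0.254	1.276
G196A	196	signaling	950	38	1	0	0.040	0.800
V186A	186	signaling	940	39	1	0	0.040	0.831
D264A	264	signaling	5726	65	0	0	0.242	1.370
D215A	215	signaling	2816	51	0	0	0.119	1.093
G144A	144	signaling	8926	31	0	0	0.377	0.660
R141A	141	signaling	7006	43	0	0	0.296	0.905
I111A	111	signaling	8728	78	0	0	0.369	1.659
D89A	89	signaling	1932	43	0	0	0.082	0.918
P237A	237	signaling	10267	80	0	0	0.434	1.701
I132A	132	no_effect	24383	71	0	0	1.030	1.510
N105A	105	no_effect	35539	67	0	0	1.502	1.424
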