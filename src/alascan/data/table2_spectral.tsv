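sample	strain	batch	target_count	standard_count	target_on_total	standard_on_total	to_standard_printed	low_abundance_bold
K29A	K29A	batch1	9	36	10	38	10	1
L34A	L34A	batch1	20	43	20	44	17	1
G31A	G31A	batch1	18	40	20	44	17	1
N41A	N41A	batch1	8	45	8	43	7	1
I63A	I63A	batch1	13	24	16	29	21	1
I86A	I86A	batch1	18	45	17	43	15	1
D89A	D89A	batch1	37	32	33	29	43	0
N105A	N105A	batch1	61	35	60	34	67	0
I111A	I111A	batch1	29	14	37	18	78	0
I132A	I132A	batch1	63	34	58	31	71	0
R141A	R141A	batch1	43	38	37	33	43	0
G144A	G144A	batch1	27	33	27	33	31	0
N190A	N190A	batch1	5	53	5	54	4	1
D215A	D215A	batch1	62	46	65	48	51	0
I233A	I233A	batch1	24	54	24	53	17	1
P237A	P237A	batch1	70	33	59	28	80	0
P262A	P262A	batch1	51	32	49	31	60	0
D264A	D264A	batch1	69	41	73	43	65	0
RbsB	RbsB	batch1	50	41	57	46	47	0
RbsB(2)	RbsB	batch2	115	46	134	54	95	0
L6A	L6A	batch2	35	0	47	0	NC	1
T10A	T10A	batch2	13	31	10	23	16	1
L88A	L88A	batch2	38	47	47	59	31	1
V106A	V106A	batch2	65	11	71	12	224	1
V186A	V186A	batch2	27	13	18	8	79	1
L195A	L195A	batch2	31	24	31	24	49	1
G196A	G196A	batch2	36	18	45	22	76	1
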