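annotation	level	subgroup1	subgroup2	subgroup3	subgroup4
gender	male	12	16	19	22
gender	female	6	5	5	13
stage	Ta	16	14	5	10
stage	T1	2	5	9	9
stage	MI	0	1	10	16
stage	Tx	0	1	0	0
grade	1	11	5	1	2
grade	2	7	11	4	10
grade	3	0	5	19	23
tp53	mut	0	4	11	14
tp53	wt	18	17	13	21
fgfr3	mut	12	11	1	10
fgfr3	wt	6	10	23	25
lund_subtype	UroA	18	15	2	9
lund_subtype	UroB	0	5	2	5
lund_subtype	GU	0	0	17	12
lund_subtype	SCCL	0	1	3	9
epitype	A	9	6	0	2
epitype	B	1	1	0	7
epitype	C	0	1	11	5
epitype	D	0	1	0	6
epitype	NA	8	12	13	15
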