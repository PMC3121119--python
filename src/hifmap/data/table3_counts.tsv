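block	matrix_id	member	c085	c080	c075
orthologous	V$HIF_STKE_2005	HSA	0	0	2
orthologous	V$HIF_STKE_2005	MMU	1	1	3
orthologous	V$HIF_STKE_2005	GGA	1	1	3
orthologous	V$HIF_STKE_2005	CIN	0	0	1
orthologous	V$HIF_STKE_2005	DRE	0	0	2
orthologous	V$HIF_STKE_2005	XTR	0	0	0
orthologous	V$HIF1_Q5	HSA	1	3	7
orthologous	V$HIF1_Q5	MMU	2	2	12
orthologous	V$HIF1_Q5	GGA	1	3	10
orthologous	V$HIF1_Q5	CIN	2	2	6
orthologous	V$HIF1_Q5	DRE	1	1	4
orthologous	V$HIF1_Q5	XTR	0	1	4
orthologous	V$HIF1_Q3	HSA	1	3	10
orthologous	V$HIF1_Q3	MMU	2	2	12
orthologous	V$HIF1_Q3	GGA	1	4	9
orthologous	V$HIF1_Q3	CIN	2	3	7
orthologous	V$HIF1_Q3	DRE	1	1	4
orthologous	V$HIF1_Q3	XTR	0	0	11
orthologous	V$AHRHIF_Q6	HSA	5	5	29
orthologous	V$AHRHIF_Q6	MMU	3	3	24
orthologous	V$AHRHIF_Q6	GGA	5	5	22
orthologous	V$AHRHIF_Q6	CIN	6	6	23
orthologous	V$AHRHIF_Q6	DRE	3	3	21
orthologous	V$AHRHIF_Q6	XTR	2	2	18
random	V$HIF_STKE_2005	HSA	0	0	1
random	V$HIF_STKE_2005	MMU	0	0	0
random	V$HIF_STKE_2005	GGA	1	1	4
random	V$HIF_STKE_2005	CIN	0	1	2
random	V$HIF_STKE_2005	DRE	1	1	2
random	V$HIF_STKE_2005	XTR	0	0	0
random	V$HIF1_Q5	HSA	0	0	3
random	V$HIF1_Q5	MMU	0	0	3
random	V$HIF1_Q5	GGA	4	5	6
random	V$HIF1_Q5	CIN	2	2	8
random	V$HIF1_Q5	DRE	2	3	13
random	V$HIF1_Q5	XTR	0	1	4
random	V$HIF1_Q3	HSA	0	0	4
random	V$HIF1_Q3	MMU	0	0	1
random	V$HIF1_Q3	GGA	4	4	6
random	V$HIF1_Q3	CIN	2	3	14
random	V$HIF1_Q3	DRE	2	2	7
random	V$HIF1_Q3	XTR	0	0	11
random	V$AHRHIF_Q6	HSA	1	1	21
random	V$AHRHIF_Q6	MMU	0	0	21
random	V$AHRHIF_Q6	GGA	5	5	20
random	V$AHRHIF_Q6	CIN	5	5	16
random	V$AHRHIF_Q6	DRE	7	7	27
random	V$AHRHIF_Q6	XTR	2	2	18
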