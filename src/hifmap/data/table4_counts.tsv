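block	matrix_id	member	c085	c080	c075
paralogous	V$HIF_STKE_2005	dre30682	0	0	2
paralogous	V$HIF_STKE_2005	dre403049	0	0	0
paralogous	V$HIF_STKE_2005	dre678512	0	0	2
paralogous	V$HIF1_Q5	dre30682	1	1	4
paralogous	V$HIF1_Q5	dre403049	0	0	3
paralogous	V$HIF1_Q5	dre678512	2	3	3
paralogous	V$HIF1_Q3	dre30682	1	1	4
paralogous	V$HIF1_Q3	dre403049	0	0	2
paralogous	V$HIF1_Q3	dre678512	2	3	5
paralogous	V$AHRHIF_Q6	dre30682	3	3	21
paralogous	V$AHRHIF_Q6	dre403049	0	0	15
paralogous	V$AHRHIF_Q6	dre678512	4	4	30
random	V$HIF_STKE_2005	G1	0	0	1
random	V$HIF_STKE_2005	G2	0	0	0
random	V$HIF_STKE_2005	G3	0	0	0
random	V$HIF1_Q5	G1	1	1	5
random	V$HIF1_Q5	G2	0	0	0
random	V$HIF1_Q5	G3	0	0	4
random	V$HIF1_Q3	G1	1	1	9
random	V$HIF1_Q3	G2	0	0	1
random	V$HIF1_Q3	G3	0	0	3
random	V$AHRHIF_Q6	G1	3	3	25
random	V$AHRHIF_Q6	G2	0	0	13
random	V$AHRHIF_Q6	G3	1	1	21
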