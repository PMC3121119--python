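reference_gene	query_species	query_gene	relation
hsa:3091	HSA	hsa:3091	ortholog
hsa:405	HSA	hsa:405	ortholog
hsa:7428	HSA	hsa:7428	ortholog
hsa:8453	HSA	hsa:8453	ortholog
hsa:6923	HSA	hsa:6923	ortholog
hsa:6921	HSA	hsa:6921	ortholog
hsa:9978	HSA	hsa:9978	ortholog
hsa:2033	HSA	hsa:2033	ortholog
hsa:54583	HSA	hsa:54583	ortholog
hsa:6513	HSA	hsa:6513	ortholog
hsa:7422	HSA	hsa:7422	ortholog
hsa:7040	HSA	hsa:7040	ortholog
hsa:5155	HSA	hsa:5155	ortholog
hsa:7039	HSA	hsa:7039	ortholog
hsa:3091	HSA	HSA_HIF1A_para1	paralog
hsa:3091	HSA	HSA_HIF1A_para2	paralog
hsa:3091	HSA	HSA_HIF1A_para3	paralog
hsa:405	HSA	HSA_ARNT_para1	paralog
hsa:405	HSA	HSA_ARNT_para2	paralog
hsa:2033	HSA	HSA_EP300_para1	paralog
hsa:2033	HSA	HSA_EP300_para2	paralog
hsa:54583	HSA	HSA_EGLN_para1	paralog
hsa:54583	HSA	HSA_EGLN_para2	paralog
hsa:54583	HSA	HSA_EGLN_para3	paralog
hsa:7422	HSA	HSA_VEGF_para1	paralog
hsa:7422	HSA	HSA_VEGF_para2	paralog
hsa:7422	HSA	HSA_VEGF_para3	paralog
hsa:7422	HSA	HSA_VEGF_para4	paralog
hsa:6513	HSA	HSA_GLUT1_para1	paralog
hsa:6513	HSA	HSA_GLUT1_para2	paralog
hsa:6513	HSA	HSA_GLUT1_para3	paralog
hsa:7040	HSA	HSA_TGFB1_para1	paralog
hsa:7040	HSA	HSA_TGFB1_para2	paralog
hsa:7040	HSA	HSA_TGFB1_para3	paralog
hsa:5155	HSA	HSA_PDGFB_para1	paralog
hsa:5155	HSA	HSA_PDGFB_para2	paralog
hsa:7039	HSA	HSA_TGFA_para1	paralog
hsa:7039	HSA	HSA_TGFA_para2	paralog
hsa:3091	MMU	MMU_HIF1A	ortholog
hsa:405	MMU	MMU_ARNT	ortholog
hsa:7428	MMU	MMU_VHL	ortholog
hsa:8453	MMU	MMU_CUL2	ortholog
hsa:6923	MMU	MMU_ELOB	ortholog
hsa:6921	MMU	MMU_ELOC	ortholog
hsa:9978	MMU	MMU_RBX1	ortholog
hsa:2033	MMU	MMU_EP300	ortholog
hsa:54583	MMU	MMU_EGLN	ortholog
hsa:6513	MMU	MMU_GLUT1	ortholog
hsa:7422	MMU	MMU_VEGF	ortholog
hsa:7040	MMU	MMU_TGFB1	ortholog
hsa:5155	MMU	MMU_PDGFB	ortholog
hsa:7039	MMU	MMU_TGFA	ortholog
hsa:3091	MMU	MMU_HIF1A_para1	paralog
hsa:3091	MMU	MMU_HIF1A_para2	paralog
hsa:3091	MMU	MMU_HIF1A_para3	paralog
hsa:405	MMU	MMU_ARNT_para1	paralog
hsa:405	MMU	MMU_ARNT_para2	paralog
hsa:2033	MMU	MMU_EP300_para1	paralog
hsa:2033	MMU	MMU_EP300_para2	paralog
hsa:54583	MMU	MMU_EGLN_para1	paralog
hsa:54583	MMU	MMU_EGLN_para2	paralog
hsa:54583	MMU	MMU_EGLN_para3	paralog
hsa:7422	MMU	MMU_VEGF_para1	paralog
hsa:7422	MMU	MMU_VEGF_para2	paralog
hsa:7422	MMU	MMU_VEGF_para3	paralog
hsa:7422	MMU	MMU_VEGF_para4	paralog
hsa:6513	MMU	MMU_GLUT1_para1	paralog
hsa:6513	MMU	MMU_GLUT1_para2	paralog
hsa:6513	MMU	MMU_GLUT1_para3	paralog
hsa:6513	MMU	MMU_GLUT1_para4	paralog
hsa:7040	MMU	MMU_TGFB1_para1	paralog
hsa:7040	MMU	MMU_TGFB1_para2	paralog
hsa:7040	MMU	MMU_TGFB1_para3	paralog
hsa:5155	MMU	MMU_PDGFB_para1	paralog
hsa:5155	MMU	MMU_PDGFB_para2	paralog
hsa:5155	MMU	MMU_PDGFB_para3	paralog
hsa:7039	MMU	MMU_TGFA_para1	paralog
hsa:7039	MMU	MMU_TGFA_para2	paralog
hsa:3091	GGA	GGA_HIF1A	ortholog
hsa:405	GGA	GGA_ARNT	ortholog
hsa:7428	GGA	GGA_VHL	ortholog
hsa:8453	GGA	GGA_CUL2	ortholog
hsa:6923	GGA	GGA_ELOB	ortholog
hsa:6921	GGA	GGA_ELOC	ortholog
hsa:9978	GGA	GGA_RBX1	ortholog
hsa:2033	GGA	GGA_EP300	ortholog
hsa:54583	GGA	GGA_EGLN	ortholog
hsa:6513	GGA	GGA_GLUT1	ortholog
hsa:7422	GGA	GGA_VEGF	ortholog
hsa:7040	GGA	GGA_TGFB1	ortholog
hsa:5155	GGA	GGA_PDGFB	ortholog
hsa:3091	GGA	GGA_HIF1A_para1	paralog
hsa:3091	GGA	GGA_HIF1A_para2	paralog
hsa:405	GGA	GGA_ARNT_para1	paralog
hsa:405	GGA	GGA_ARNT_para2	paralog
hsa:2033	GGA	GGA_EP300_para1	paralog
hsa:2033	GGA	GGA_EP300_para2	paralog
hsa:54583	GGA	GGA_EGLN_para1	paralog
hsa:54583	GGA	GGA_EGLN_para2	paralog
hsa:7422	GGA	GGA_VEGF_para1	paralog
hsa:7422	GGA	GGA_VEGF_para2	paralog
hsa:7422	GGA	GGA_VEGF_para3	paralog
hsa:6513	GGA	GGA_GLUT1_para1	paralog
hsa:6513	GGA	GGA_GLUT1_para2	paralog
hsa:6513	GGA	GGA_GLUT1_para3	paralog
hsa:7040	GGA	GGA_TGFB1_para1	paralog
hsa:7040	GGA	GGA_TGFB1_para2	paralog
hsa:7040	GGA	GGA_TGFB1_para3	paralog
hsa:5155	GGA	GGA_PDGFB_para1	paralog
hsa:5155	GGA	GGA_PDGFB_para2	paralog
hsa:7039	GGA	GGA_TGFA_para1	paralog
hsa:3091	XTR	XTR_HIF1A	ortholog
hsa:405	XTR	XTR_ARNT	ortholog
hsa:7428	XTR	XTR_VHL	ortholog
hsa:6923	XTR	XTR_ELOB	ortholog
hsa:6921	XTR	XTR_ELOC	ortholog
hsa:2033	XTR	XTR_EP300	ortholog
hsa:6513	XTR	XTR_GLUT1	ortholog
hsa:7422	XTR	XTR_VEGF	ortholog
hsa:7040	XTR	XTR_TGFB1	ortholog
hsa:3091	XTR	XTR_HIF1A_para1	paralog
hsa:405	XTR	XTR_ARNT_para1	paralog
hsa:7422	XTR	XTR_VEGF_para1	paralog
hsa:7422	XTR	XTR_VEGF_para2	paralog
hsa:6513	XTR	XTR_GLUT1_para1	paralog
hsa:6513	XTR	XTR_GLUT1_para2	paralog
hsa:7040	XTR	XTR_TGFB1_para1	paralog
hsa:7040	XTR	XTR_TGFB1_para2	paralog
hsa:3091	DRE	DRE_HIF1A	ortholog
hsa:405	DRE	DRE_ARNT	ortholog
hsa:7428	DRE	DRE_VHL	ortholog
hsa:8453	DRE	DRE_CUL2	ortholog
hsa:6923	DRE	DRE_ELOB	ortholog
hsa:6921	DRE	DRE_ELOC	ortholog
hsa:2033	DRE	DRE_EP300	ortholog
hsa:54583	DRE	DRE_EGLN	ortholog
hsa:6513	DRE	DRE_GLUT1	ortholog
hsa:7422	DRE	DRE_VEGF	ortholog
hsa:7040	DRE	DRE_TGFB1	ortholog
hsa:5155	DRE	DRE_PDGFB	ortholog
hsa:3091	DRE	DRE_HIF1A_para1	paralog
hsa:3091	DRE	DRE_HIF1A_para2	paralog
hsa:3091	DRE	DRE_HIF1A_para3	paralog
hsa:3091	DRE	DRE_HIF1A_para4	paralog
hsa:405	DRE	DRE_ARNT_para1	paralog
hsa:405	DRE	DRE_ARNT_para2	paralog
hsa:405	DRE	DRE_ARNT_para3	paralog
hsa:2033	DRE	DRE_EP300_para1	paralog
hsa:2033	DRE	DRE_EP300_para2	paralog
hsa:54583	DRE	DRE_EGLN_para1	paralog
hsa:54583	DRE	DRE_EGLN_para2	paralog
hsa:7422	DRE	dre:30682	paralog
hsa:7422	DRE	dre:403049	paralog
hsa:7422	DRE	dre:678512	paralog
hsa:6513	DRE	DRE_GLUT1_para1	paralog
hsa:6513	DRE	DRE_GLUT1_para2	paralog
hsa:6513	DRE	DRE_GLUT1_para3	paralog
hsa:6513	DRE	DRE_GLUT1_para4	paralog
hsa:7040	DRE	DRE_TGFB1_para1	paralog
hsa:7040	DRE	DRE_TGFB1_para2	paralog
hsa:7040	DRE	DRE_TGFB1_para3	paralog
hsa:5155	DRE	DRE_PDGFB_para1	paralog
hsa:5155	DRE	DRE_PDGFB_para2	paralog
hsa:3091	CIN	CIN_HIF1A	ortholog
hsa:405	CIN	CIN_ARNT	ortholog
hsa:7428	CIN	CIN_VHL	ortholog
hsa:8453	CIN	CIN_CUL2	ortholog
hsa:6923	CIN	CIN_ELOB	ortholog
hsa:6921	CIN	CIN_ELOC	ortholog
hsa:9978	CIN	CIN_RBX1	ortholog
hsa:2033	CIN	CIN_EP300	ortholog
hsa:7422	CIN	CIN_VEGF	ortholog
hsa:3091	CIN	CIN_HIF1A_para1	paralog
hsa:3091	CIN	CIN_HIF1A_para2	paralog
hsa:405	CIN	CIN_ARNT_para1	paralog
hsa:405	CIN	CIN_ARNT_para2	paralog
hsa:7428	CIN	CIN_VHL_para1	paralog
hsa:2033	CIN	CIN_EP300_para1	paralog
hsa:7422	CIN	CIN_VEGF_para1	paralog
hsa:7422	CIN	CIN_VEGF_para2	paralog
hsa:7039	CIN	CIN_TGFA_para1	paralog
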