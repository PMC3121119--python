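node_id	label	reference_genes
K08268	HIF1A	hsa:3091
K09097	ARNT	hsa:405
K03871	VHL	hsa:7428
K03870	CUL2	hsa:8453
K03873	ELOB	hsa:6923
K03872	ELOC	hsa:6921
K03868	RBX1	hsa:9978
K04498	EP300	hsa:2033
K09592	EGLN	hsa:54583
K07299	GLUT1	hsa:6513
K05448	VEGF	hsa:7422
K13375	TGFB1	hsa:7040
K17386	PDGFB	hsa:5155
K08774	TGFA	hsa:7039
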