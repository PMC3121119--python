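species	gene_id	window	start	end
HSA	ENSG00000119630	GGCAGGCGTGCAGACTCA	-963	-946
HSA	ENSG00000119630	TGTGTCCGTGCCTGGCTA	-1392	-1375
HSA	ENSG00000119630	GCCCCTCGTGGGTGGGCA	-628	-611
HSA	ENSG00000112715	TGAGGACGTGTGTGTCTG	-517	-500
HSA	ENSG00000112715	TGCATACGTGGGCTCCAA	-982	-965
HSA	ENSG00000112715	TGTGTGCGTGTGGGGTTG	-485	-468
HSA	ENSG00000173511	CGAGATCGTGCCCCGGGG	-641	-624
HSA	ENSG00000173511	GGAGCGCGTGTCTGGGTC	-277	-260
HSA	ENSG00000173511	CTCACGCGTGCCACGGAG	-1601	-1584
MMU	ENSMUSG00000004791	TGAGCACGTGTGGATCCT	-542	-525
MMU	ENSMUSG00000004791	CCAATCCGTGTGTGCTCA	-204	-187
MMU	ENSMUSG00000004791	ATGTCACGTGAAATGACG	-122	-105
MMU	ENSMUSG00000023951	TGCATACGTGGGTTTCCA	-1082	-1065
MMU	ENSMUSG00000023951	AGTCTGCGTGAGGGAGGA	-1538	-1521
MMU	ENSMUSG00000023951	TGAGTGCGTGCATGCATG	-1570	-1553
MMU	ENSMUSG00000024962	TCCCCTCGTGAGGCAGCG	-1799	-1782
MMU	ENSMUSG00000024962	ACTACACGTGCAATAAAC	-1726	-1709
MMU	ENSMUSG00000024962	GTCAAGCGTGCTGAGGCC	-287	-270
GGA	ENSGALG00000010290	CCCCGACGTGCGGAGCGG	-1970	-1953
GGA	ENSGALG00000010290	TGGCACCGTGCTGGAATA	-143	-126
GGA	ENSGALG00000010290	CCCCATCGTGCAGCCCCA	-208	-191
DRE	ENSDARG00000034700	CCTGTACGTGGTGATGGA	-997	-980
DRE	ENSDARG00000034700	TATCGTCGTGTTGTGATT	-1106	-1089
DRE	ENSDARG00000034700	TTAAACCGTGTGCGCTGC	-55	-38
XTR	ENSXETG00000016375	TGTCTCCGTGTAATCGCG	-1289	-1272
XTR	ENSXETG00000016375	TAATCGCGTGCTGATAAC	-1273	-1262
CIN	ENSCING00000014020	CAGATACGTGATCTTGGT	-1977	-1960
CIN	ENSCING00000014020	TTACGACGTGGACATTCC	-1475	-1458
CIN	ENSCING00000014020	CGCCATCGTGCGAAGGCA	-150	-133
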