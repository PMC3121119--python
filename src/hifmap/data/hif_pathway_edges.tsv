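source	target	relation
K09592	K08268	hydroxylation
K03871	K08268	ubiquitination
K03870	K03871	complex
K03873	K03871	complex
K03872	K03871	complex
K03868	K03871	complex
K09097	K08268	dimerization
K04498	K08268	coactivation
K08268	K07299	activation
K08268	K05448	activation
K08268	K13375	activation
K08268	K17386	activation
K08268	K08774	activation
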