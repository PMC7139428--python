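mirna	logFC	p_value	fdr	direction
rno-miR-141-3p	2.49	<0.001	<0.001	up
rno-miR-200a-3p	-1.41	<0.001	0.037	down
rno-miR-200c-3p	2.51	<0.001	<0.001	up
rno-miR-208b-3p	-1.56	<0.001	0.012	down
rno-miR-293-5p	-1.99	0.001	0.045	down
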