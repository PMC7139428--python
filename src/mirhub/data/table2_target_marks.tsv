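gene	name	rno-miR-141-3p	rno-miR-200a-3p	rno-miR-200c-3p	rno-miR-293-5p
Nr3c1	Nuclear receptor subfamily 3 group c member 1	1	1	1	0
Jazf1	Juxtaposed with another zinc finger protein 1	1	1	1	0
Rap2c	RAP2C, member of RAS oncogene family	1	1	1	0
Zkscan1	Zinc finger with KRAB and SCAN domains 1	1	1	0	1
Pank3	Pantothenate kinase 3	1	1	0	1
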