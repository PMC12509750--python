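protein	charge	xcorr	identified_both	location
TOM40	3	5.42	Yes	Outer mitochondrial membrane
QCR6	2	1.48	Yes	Inner mitochondrial membrane
DTX1	2	2.37	No	Cytoplasm, nucleus
ZNF24	2	2.12	Yes	Nucleus
NID2	4	1.93	No	Secreted protein
LTBP4	3	1.90	No	Secreted protein
MALT1	3	1.59	Yes	Cytoplasm, nucleus
PKHA8	2	1.35	No	Golgi apparatus
EXOSX	2	1.09	No	Cytoplasm, nucleus
VP13A	2	1.02	No	Membrane protein
YD021	2	0.94	No	Unknown
CA094	2	0.78	No	Unknown
GASR	2	0.75	No	Cell membrane
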