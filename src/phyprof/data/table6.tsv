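	C1A_generic	cathB	cathC	cathX	cathL	cathF	cathH	p26_29	type1_long
LECA	0	1	1	1	1	1	1	1	1
FECA	1	0	0	0	0	0	0	0	0
Alphaproteobacteria	1	0	0	0	0	0	0	0	0
Cyanobacteria	1	0	0	0	0	0	0	0	0
Deltaproteobacteria	1	0	0	0	0	0	0	0	0
Archaea	1	0	0	0	0	0	0	0	0
LUCA	1	0	0	0	0	0	0	0	0
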