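	cathB	cathC	cathX	cathL	cathF	cathH	p26_29	type1_long
Diaphoretickes	1	1	1	1	1	1	1	1
Amorphea	1	1	1	1	1	1	1	1
CRuMs	1	1	1	1	1	1	0	0
Ancyromonadida	1	1	1	1	1	0	1	0
Malawimonadida	1	1	1	1	1	0	1	0
Discoba	1	1	1	1	1	1	1	1
Metamonada	1	1	1	1	1	0	1	1
LECA	1	1	1	1	1	1	1	1
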