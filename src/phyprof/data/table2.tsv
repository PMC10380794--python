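	cathB	cathC	cathX	cathL	cathF	cathH	cathO	p26_29	type1_long	vWFA_C1
Metazoa	1	1	1	1	1	1	1	1	0	1
Choanoflagellata	1	1	1	1	1	0	1	1	0	1
Filasterea	1	1	1	1	1	0	1	0	0	0
Tunicaraptor	1	?	1	1	1	0	1	0	1	0
Pluriformea	1	1	1	1	0	1	1	1	0	0
Ichthyosporea	1	1	1	1	1	0	1	1	0	0
Rotosphaerida	0	0	0	0	0	0	0	0	0	0
Fungi	0	0	0	0	0	0	0	0	0	1
Breviatea	1	1	1	1	1	0	0	1	1	0
Apusozoa	1	0	0	1	1	1	1	1	0	0
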