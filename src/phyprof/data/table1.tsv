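	cathB	cathC	cathX	cathL	cathF	cathH	p26_29	type1_long
Chloroplastida	1	1	1	1	1	1	1	0
Glaucophyta	1	1	1	1	1	1	1	0
Rhodophyta	1	1	1	1	1	1	1	0
Picozoa	1	1	1	1	0	0	1	0
Cryptista	1	1	1	1	1	1	1	0
Haptophyta	1	1	1	1	1	1	1	1
Centroheliozoa	1	1	1	1	1	1	1	1
Provora	1	1	1	1	1	1	0	0
Hemimastigophora	1	1	1	1	1	0	1	1
Telonemia	1	1	1	1	1	0	0	0
Stramenopiles	1	1	1	1	1	1	1	1
Alveolata	1	1	1	1	1	1	1	1
Rhizaria	1	1	1	1	1	1	1	1
Amoebozoa	1	1	1	1	1	1	1	1
Obazoa	1	1	1	1	1	1	1	1
CRuMs	1	1	1	1	1	1	0	0
Ancyromonadida	1	1	1	1	1	0	1	0
Malawimonadida	1	1	1	1	1	0	1	0
Discoba	1	1	1	1	1	1	1	1
Metamonada	1	1	1	1	1	0	1	1
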