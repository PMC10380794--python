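	single_domain	multidomain
Acidobacteria	1	1
Aquificae	1	1
Atribacterota	1	1
Caldiserica_Cryosericota	1	1
Calditrichaeota	1	1
Chrysiogenetes	1	1
Coprothermobacterota	1	1
Deferribacteres	1	1
Desulfobacterota	1	1
Dictyoglomi	0	0
Elusimicrobia	1	1
FCB_group	1	1
Bacteroidetes_Chlorobi	1	1
Fibrobacteres	1	1
Gemmatimonadetes	1	1
Fusobacteria	1	1
Myxococcota	1	1
Nitrospinae_Tectomicrobia	1	1
Nitrospirae	1	1
Pseudomonadota	1	1
PVC_group	1	1
Chlamydiae	1	1
Lentisphaerae	1	1
Planctomycetota	1	1
Verrucomicrobia	1	1
Spirochaetes	1	1
Synergistetes	1	1
Terrabacteria_group	1	1
Actinomycetota	1	1
Bacillota	1	1
Chloroflexi	1	1
Cyanobacteria	1	1
Deinococcus_Thermus	1	1
Tenericutes	1	1
Thermodesulfobacteria	1	1
Thermotogae	1	1
Bacteria_candidate_phyla	1	1
Asgard	1	1
Thermoplasmatota	1	1
DPANN	1	1
Euryarchaeota	1	1
TACK	1	1
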