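((Acidobacteria,Aquificae,Atribacterota,Caldiserica_Cryosericota,Calditrichaeota,Chrysiogenetes,Coprothermobacterota,Deferribacteres,Desulfobacterota,Dictyoglomi,Elusimicrobia,(Bacteroidetes_Chlorobi,Fibrobacteres,Gemmatimonadetes)FCB_group,Fusobacteria,Myxococcota,Nitrospinae_Tectomicrobia,Nitrospirae,(Alphaproteobacteria,Deltaproteobacteria)Pseudomonadota,(Chlamydiae,Lentisphaerae,Planctomycetota,Verrucomicrobia)PVC_group,Spirochaetes,Synergistetes,(Actinomycetota,Bacillota,Chloroflexi,Cyanobacteria,Deinococcus_Thermus,Tenericutes)Terrabacteria_group,Thermodesulfobacteria,Thermotogae,Bacteria_candidate_phyla)Bacteria,(Thermoplasmatota,DPANN,Euryarchaeota,TACK,Asgard)Archaea)LUCA;
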