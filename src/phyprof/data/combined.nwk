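((Acidobacteria,Aquificae,Atribacterota,Caldiserica_Cryosericota,Calditrichaeota,Chrysiogenetes,Coprothermobacterota,Deferribacteres,Desulfobacterota,Dictyoglomi,Elusimicrobia,(Bacteroidetes_Chlorobi,Fibrobacteres,Gemmatimonadetes)FCB_group,Fusobacteria,Myxococcota,Nitrospinae_Tectomicrobia,Nitrospirae,(Alphaproteobacteria,Deltaproteobacteria)Pseudomonadota,(Chlamydiae,Lentisphaerae,Planctomycetota,Verrucomicrobia)PVC_group,Spirochaetes,Synergistetes,(Actinomycetota,Bacillota,Chloroflexi,Cyanobacteria,Deinococcus_Thermus,Tenericutes)Terrabacteria_group,Thermodesulfobacteria,Thermotogae,Bacteria_candidate_phyla)Bacteria,(Thermoplasmatota,DPANN,Euryarchaeota,TACK,(Asgard,(((Chloroplastida,Glaucophyta,Rhodophyta,Picozoa,Cryptista,Haptophyta,Centroheliozoa,Provora,Hemimastigophora,Telonemia,(Stramenopiles,Alveolata,Rhizaria)SAR)Diaphoretickes,(Amoebozoa,((Metazoa,Choanoflagellata,Filasterea,Tunicaraptor,Pluriformea,Ichthyosporea,Rotosphaerida,Fungi)Opisthokonta,Breviatea,Apusozoa)Obazoa,CRuMs,Ancyromonadida,Malawimonadida)Amorphea,(Discoba,Metamonada)Excavata)LECA)FECA)Eukaryomorpha)Archaea)LUCA;
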