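((Chloroplastida,Glaucophyta,Rhodophyta,Picozoa,Cryptista,Haptophyta,Centroheliozoa,Provora,Hemimastigophora,Telonemia,(Stramenopiles,Alveolata,Rhizaria)SAR)Diaphoretickes,(Amoebozoa,((Metazoa,Choanoflagellata,Filasterea,Tunicaraptor,Pluriformea,Ichthyosporea,Rotosphaerida,Fungi)Opisthokonta,Breviatea,Apusozoa)Obazoa,CRuMs,Ancyromonadida,Malawimonadida)Amorphea,(Discoba,Metamonada)Excavata)LECA;
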