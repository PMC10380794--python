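>cathF_seed1
VGWFNHKCATFLSEESASRHNAGCRVQDVRQILMNMSKCQRKIKRCRECVMQPLPLSEAPGTAYEFRYSYGAWRTPWEHYATKQPCPPLPQLLHAYNDNQISHYIDKAGLATTDWENWIAEHCMVMKVVRIEIDTPNNGMNWRLWVTCAYDCKVHGPSFEQSIAYGANWCIVFYHACKQFHQEPSGRENFPYMVAIRCPHYWNLLGWGDG
>cathF_seed2
LGAFNHYRAHASSVHSKSDFCVGCRVQWVRQILRNWCKDLPKAKRCRDKVCQPLPSSEAPYVDYQFNVQKPAFWTIHEHYLDYQPCLPLGWLLHYYNDNQISHVIWKELLAMTEWEQGAWELQMVVHEVRTEGNMWNNWMNERDWVRHAYDCKVHGRSFMDSIVYGANWRIVFCHADLSFHVEPWVRENGQYMVAIRCPMYWNDLMQGRD
>cathF_seed3
VGVRAFLCAPFLSEESAPRMNASCQVVGVRFLLMQECKCQRCPVRCRECVMQQLPLTEMPGRAMSFYYSTGAWRTPNETRQMATECMSAPELCLGYNDWEIIPYADKAGHATTDNENWPAEHCKIMKVVRYSIWMPNTGMGWRNLVTMWPRMYVHCFKAEQSIAKGKNWVFVFMHASAHIHPEPSGIENFIMTVAILCPIGANYLGHGDG
>cathF_seed4
GGAFNHKRAQFLCNCRACERCAGCRSRHARTILPNMRKDQYKILWDREPQYQDRPLSDASGYSVEDRRYYGEERTPWEHFATKQPCPPLPTNPHFWNNMHINFYYQKYGAEIREYENWAVWSCMVVTVFQPENIVLPLGYKWCRYITCMYDNNVHGCSFEQFIYYGACWNIQRYHECKQFHRFWSGDLQFNYTVAPECRHYWNLGPWGDA
>cathF_seed5
VEWFNYKCATFLDEFSASIHNAGCLVQSALQILANCIKNQSWTKMCVTTVMQPLKLTEAEGTTYAMAYEYAFWRNFIGHHAAKQPCPPLPQGVHLSNTGQISVYFNKDGLATQAWEGWIAECLLVDKQPWIERTTPFNHMDWRLWVGCFDDLKVHKNHIYQSICNKANRKIVFDHRCKQMHAETKGRYPFPYYVAIEGPYQSNENGWGLC
>cathF_seed6
VGYFKHKDALYLVEEKDSRHVAGKRVQDARWYRMLMRMCCRYIDSCNEGCMSPLINSRAPGTAYEFRYSNHALVTMWEPYATKPPCPLLEMLLFAYNENQSGLYIDKAGWTYTCWYNWHAEWLYGMKVNRIEYSTVNNGFNWRPWCAVAYDCQNNDPRFGGSPRQGANWCLVKLHACKQFHLRTGFRCNFWYEDAPVCPYWWNLLGWGDG
>cathF_seed7
VGGQNYKCALAKHTESASRYNAGCEVYWVCQILGNMSACQRKYSICVECIHQCLMISEAPGPAYHSNYSCGAQRTPWEHYAQPQFCPHQMQKLHAYNENQISIYIMKQGLFITWSEPWLAEHSNVSKVVRIEEDTTNNGMNWELWVWTAYIPYRHGPSQEQSIFSGANWCIVFWSFCKQGHQEPTAHDNHPYMDAIRIPHKWNLCGWGSG
>cathF_seed8
VWWLNEKCADAYSEFSGSRHSAMLRGSDKTLSHMNWSKFMLAINRCGRAQRQPLPCSEAGDHAPENEYSYGSWRTPDFHYATPLNCPPLYNDLAYYNSNQISHYIHKNMGAETDWERRIAEHCVVMWAVRMEIHNWNNMIYTRPWRTCVYDCEVWGPSFKSNSATGAHRHIDWYHFNCQFHLEPSGRDNIFYHNRITPWYYQNDLGWPDC
>cathF_seed9
QGWFNTKCNLMLTENDASRHGEWCRWAVVRQDVMNYSAFARKIAWFRNHVMCPLQLSEAPGTHREFRKSNGAERTPWEHYHTPQWCWPWVEVCQAYRDPQISHKCVPAPYATTDAENDQAFHCMVMKYVRIAIDWPENPMGEPLWKTSAADYKVGGPSQEVNSQYGAFACIDFGHNDKVSHHEPPVREVFPYMVAIRCPNYWNLLGWGWG
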