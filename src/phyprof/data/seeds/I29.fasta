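>I29_seed1
VGWFNHKCATFLSEESASRHNAGCRVQDVRQILMNMSKCQRKIKRCRECVMQPLPLSEAP
>I29_seed2
VGYWRTLCATFLSETSAHMRNWFYWVQDVRQILYWESKSSCKFKVCREDVMFVLPGFETV
>I29_seed3
VYWFNYKYECFIVEEGASVMNAGCRVFDCRQISWYMSKCQLSITSQPPSKQQLSPNSQRY
>I29_seed4
VGLFIRFKASFLFNTSAPRSNVGCNVDDVWQILMRKHSIQRKTVLYRWLVMQALPLSESP
>I29_seed5
WGWFNHKCADFSSCKSASMGQASSRVQDDRQQLKNMSKHQYFIKCIDQRHMKPLFKSEPV
>I29_seed6
TGWFRHICALLKSEESWNRNMQGCRVQDGRQILMNRENQQKFILRCEEQVNQPTPLSEAP
>I29_seed7
EVWFNHKCKTIPEEEPGSRDNQGHQPQDNRACSMPRSACQMEIQRMRECVHQPLESLRAA
>I29_seed8
VGIFFHTCVVFYSNETANSANAGCRWQDVRQIGMNQLKSQRKCKYKRECVFKPLGFSEAH
>I29_seed9
VGWLNLKWTTFANCESMRCLFACIRHFRRQQCWLSSSKCQVKIKWCRECSWQELILSAAP
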