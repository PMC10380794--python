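>cathC_seed1
PCKHLNRLQMIWQHEYGWQLVECSGCESDIWIYANFWCTCFEHQWCTTYDGVQRIYIICIMAIIYSVYPFYRDNHETCMHIYRWRNFWTAHVVNRSWYLRRNVKMDNPTFCIEDECDREPHKMWHQIILPALIEGNVEQSWSNTCPAMQA
>cathC_seed2
VIYHLMRLDLIWRHEYGWSLVETSVCQLTIWEHARPRCRKFNHQQVTYVDCVQREYIICYMAIIYDVYKFYRSYHITCICKYRWRMFWGNHVRNRTVYLRRNVLMMIITGLHIEERDMIGHKMNTQQTLYMLWERIVELFWSNPWPAFQA
>cathC_seed3
PYWTLNYYKHIWLHEYGQQIGEWFGCCSHKECQAHFWPTPNEEWRRTFYDMVQRMYINCITAIFKTVYNFRDDNHPECMHINVWRVFMTNPVVNRSWALPQMVKVWNPTFWIEDECDRFPHKMWMQIIFNALIEGCGMQLWSNTVPLYAR
>cathC_seed4
VCDHRNGLKMIWQHFPGWQLVWQSGCESCIAIAANWDNVRFEHQWYTIYDHWVRVARICGMAIEYSPYPFYRDQHYTKEHPMRWRKSHATEQNNCSMYLRRNNKMSIEFFCIEDESEPGHHREVPQIIWPYNISNNWEQSNSNTCPTDVA
>cathC_seed5
KCKGQNRVHAIPQYEIFWQEVHCVGCEPDIWISPNRWVNMFYYQWCTTQFGVQREYQFCIMAIFVHHSAFIRDNVECAWTIYHWRANMFPHVVNRGWPLRRNYKMDQPTFCCEALCAREPHKAQHLMIAPASWHGHVWQSTANTHLAMQQ
>cathC_seed6
PCLHLDSNNDYWRHNQGWQLLACSGCHSDYWIYPLHHCTMFRHQKCETDDTVQRMYIFLIRAIILSTCPFFRDTHKQWHHWYRMRNFATEHVVNKQWRLVRNSHFTWPTFMTEMEVMREPHTGWHQIILMALILGNVTDSVINTCPAMCA
>cathC_seed7
PCKHLIRMSADSQEECGGQLVECWGCEWDNWIYASFWCGCFEAFWCTIYDGVQLKYQIYIAAPICSQKPFDGDNHETCMNIHRWCNIWTDHVGGSSWYLRENVPMFEPTACIADPVDTVEHKMWHQIWSPALYLYNWEQSKSNTCPVMQC
>cathC_seed8
PCGHLNRNQMIWQHAKGWQDAEDSYCECWPCVCAIFKCYTFEHCWSIVRDGILRIFIDVIAAIVYSVYPEARDASITCNCIMDTRNMWTAFVVTRSIYLRNNHWMDNEFFKIEDEWNSDPHRETHQITDPALIDGNVCQSWSNTCEIWQA
>cathC_seed9
PCKHLCVLQIIVQENYGWWPNEMLHCESDIWSYAISWEYCFEHQWCTTHERCSRRYEICHMGIYYEVYQFYLSNHELCMHPYRWENYELWHQSGQIWYCRRNVKMDNPPFSIEDYDFYEPHKMRHNEIHSALTEGNVKPKWGNGCIYMRA
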