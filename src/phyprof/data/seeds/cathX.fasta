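>cathX_seed1
IGPAAFETENHKMYLSHMRRWMEHPCYMVCWCPHVAYRGYGWMMADLEEERHDHWKPQCNGNHKAKQCNCFASRYLSNADCYWDCRYDFLDVENDDNHVVVLRGIMMWTYCTAMPQKPIAHMNEMGNFDISMLHNGFAQRWANAPEGMSH
>cathX_seed2
IGPLPFETRYCKLHYVHMRRSMFHLCYMGCWCSHVQLTPFVWMMADLEEENDTHWKFQCQYLDKAHQCNVFPSRYSPNADWYWDCRYDFLTVEEVYDMVDVLRGLMAWTACTAMPQKPFAHMNEMGNFDISMGSKQYAQRWNNAGEAMTH
>cathX_seed3
IAPAYFETLNQCWGLYYMPRWSEHACYMYCVMHHVCYDGYGWTVARLEDIRHDGWRPQVNVNHKAKFGKFLAMRMCSNADCYWDCRYDFLKVENRQLFVEFMMGIQMWGYYTRTIQKDVAHMNWHGNFDISILHNGYACRVANADEGMSH
>cathX_seed4
IGPAWFEMDNWVHYLSHDRRHMEWPCYMVCWCLHVWYIGPGHLVADQFEIWYQHWKRNMPGNQKAKYCRQHASMYLNDACMYWYCKYDFLDVENWDNHVVVCPGIGWWCYPEGNRSKPFAHENEMNLFDRSCPHEAFMQRWANQQIAWIH
>cathX_seed5
TGRRAFESEHYKSPLSPCHRWMKNPCEFVCFHPPHAYVGDECDMMAMHEYNQRHNMPQCFRNHKNKKDPPFMSSYLPHADSYWDNRYGFLCVSYYDELIVHLQEIIMSHYQTAFPVFQIEHIYEMMNVDLSMLHNDFAGPWDNAEYWMSH
>cathX_seed6
IGPAALETEPWWDYLCHMRTWWETMCVMVCNCSHVAVRGSWPMIADLLCERCDHWKWWCNFLHKAKQYNLFHSRLLSCAAMDWDCRYCFICVENDENHGHIHRGAHMWNYRYALVQVCIWHANLMSCFDNSDLLCNFDQRRKNDTTHMSH
>cathX_seed7
YGDWAFESEWHKRYVSHKRQVMMYKCDMICWAPQVPWRYPGWCMADREEERYDAMKPQTMGLNKAMQCHSDASCSLSNADFYMSYSEAFCAYENCDNWYVLLHGHMMRCYCTIMPQKEIAHMNENGTCSIPMKHNGFAPIKANAPEGMSQ
>cathX_seed8
IFYFTFEMEHPKTYGSHAMEWMELPCYGVCWRPYVAMRGRGWRMAHNSEEHHDLCKEMANGMFKAKNCNPRQSRHLSCADCYIACSYVMECVTNCDGHVVVFYGIMMWTYETARPQKPGAHMVEVGVFSIDWDHRHFWQRLANMAECMSW
>cathX_seed9
IHTAKAHYENIGMYLYHYCRWQEHPCYCVDWCMHVAFRGYGNMMQVLCHERHGHQVPQDGCNGVGKNCDIFWSDRLSNFDCYWMIRAERQDGENDDNHVVSLPDIIVGPHCTHQPQWPIAHGNEMVMFDISNLHRCGMQVIENQVGRDSH
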