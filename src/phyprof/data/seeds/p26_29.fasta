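>p26_29_seed1
VGWFNHKCATFLSEESASRHNAGCRVQDVRQILMNMSKCQRKIKRCRECVMQPLPLSEAPNTGARVLWNEHFDQDQMLQHEHDKPCHSFPASYPTWYMQSWTHWEDSIESSDRGRSLERGQWEPDTVGMWGPSDLGIMHCDCVYAPGPYVNMKQCGAKFCVAQQYGRKKIYFISELWVKWHNRCAYELAFMIDWADAQFMRVNASRINNC
>p26_29_seed2
VYVHIYHHHKETSRKCASRENAGCRVQDVRYLHMDMLKCQRKIKRCEVCTAQPLPLSEMKWTGMGLDWASMEYQHQMLPMTHHKPCQKFPASYRTWYMQPWTHWEDLIESSDSGLSKTRFQTEYDAVWEPGHSDLGFWSCDCGSIEQNPVYPWQVIAKRWVAQQYGRKKIDFISEAHWKWHDRYASEIAKRGDWMKAQTMRVNASAINNC
>p26_29_seed3
TNWWNHKCQDDSSFESASRHFQGCRVQDVRKILYKMSLCYSKIRRIRECVFQYLPLSDAPRTRAYVLWNWHYDQKLMLQHEFDKPCHSFRANYCCQGEQFWTHWRANIVSNDRGRSKARDQWSANTWQMWVWSDLGICHCDWVDAPGPCVVFKTCYAGFERSCQIGRKQIKFEDYLTSGTHYRGAYELHFMIWLGAAMFMRVNASRMNQC
>p26_29_seed4
YFEYDHKNATFNQYESASFENLGCEVQQVIQYYQNMSQNHRQILRLRECVDYKLPDSIGPNTGGRWLWNGMKFQPQMFNHEHEQPCCAGMPSYYLWYHLSNTFNDNMSEASARGMTLEFGMNEMDTVHMWGPSDRGTCICYCEYAPVPYINMGQCLAKFCSALQYTFKIRQPIKELWFGWHERCAYEQQFMFEQADAQCMQYNCDATNNC
>p26_29_seed5
VGWMNYCCATFSAHESASYHRAGCRFADFVQICHFRKECQAQIGRNDEFCPQPLPDSEATNWCARVLWNQLADRDGHLQHEHDKPCISFPASYQQWYMAQKAHWEDEWESSLSGRSTLTAQFLPDTEYHDCESDRGIMHFFCLGAPTPCVNMKQTFAEECVAEEYGRHKIYQISENWVMTHMRCAYPLAFMTDWDKAQFMRVNACNINMC
>p26_29_seed6
VGWCEPKCLTCSSEEVASVKNAGLRKPFDVQGMMNKSLCKRKIKCGRGWVMMYLPASEAPNTGWAVNPCIHFDQDEMMQWAHLKPCHSMPAMYPTWMMQSLTFWVCSSYSSNDVYSLERGQGFPGRQGMLGPRHLGIFHNICVYAYGFRVNRNGCHAKPGNACQYGGKEIMFIGEGHVKWHNRMVYELAFSIDQADAQFMRVNAQHIHLT
>p26_29_seed7
VGTFCHKHATPLSHESISRANAGCSWQDRRIHLRDMSELQSKIMACRECVMQPLPAMEAFPQWKDVLWNCIYDHCGDNWEGISRPCLSFNASYARSFMQSDTLWEDRRESSRRGRSIWRNAGEAMNVGMWRQSVKGSMHCDCPEAEGVMVVMKQMWAMLLVWHQYGRTKIYRIQNLEVYKHCRCAIELYFRIDWNDAQFHRCNARRHNNW
>p26_29_seed8
AGWRGQKQARHTSIESLFTHNAIVVVQNYSPILMNQVKCNPMHQRGRDKVHHANPLKWWWNTGARVWFWEDFVQKPMEQHEHAPACTRFRASYVTWDMRSWTHNEDNCNSSYRGRSFEGGTWECNTSGFWGPVDFGHMHCDCVYAPYPAVVMKGRAAKCTPTDQYGRECSHQIEELWCKWHNRCAYETADMIFWASAPFMRNNASDMNMC
>p26_29_seed9
YGWFMFVQAAFLSIESASFIAFGGRVRHVRQILMNVEVCYRHWKMTRSCVIQPLGLSEAGNTGDRVLWNEHIDQDQEVQHEQSKLCHTPGESSPTWNMPSWTPWSDFKEQRTRFGSCERGQWEPDTVGCSEPSDRVIMHCDGVVMPGPWALPCQCGWDQCVYWQYTRKRIYFHSELRYWWHALCDYELEKKTDWADYYFFVHNMSWDCNC
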