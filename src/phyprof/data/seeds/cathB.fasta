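>cathB_seed1
HELACITIEKKLNICTTGDPAKLAQCFGFYFLFTDIGCSRGCYYIRTPTCGKSMWSKVYTDYTLHNEAHVCLLSWNNSKYWSLDNQHFLLKIKIWGDYKCRIRESMFHFEMQGITAAPSRHMMYFVTLSMVWLFRKHPVKKDNRDGLPYL
>cathB_seed2
TEMACWTIEKKTLICITGRSAKLAQCFGDYFLFNCYMCSHGCYYCYWKTCGKEMWSWAYTDDTTHPEGHICLLSWMNSEYYSLNAQHDIKKIKVWYTFKCRIRWHMDHFEMQGITLAPHRHAMYFKSQGMVTRLRKEECKKKNPEGLTTL
>cathB_seed3
HDLACITDTKKLCIHTCGDYAKLAWCFRFYFLNTDPGCSDCCCYIPTWQQGPCQWSVVYTPPNLNWSAHGCLQSNNGSMMQSGDNQKMLLIIKIWMDYTNRIRESGMHTSMQFRTGAPSQHMFYFVTLSYVWWFRPHPCKDDNRQGLYDE
>cathB_seed4
IPLACITCEKKPNIPKTSYRGNQALCFGFYELFTDIGKSIPCYYIRYPFHYCFKHSKIYHAYTAQNEAHGKQLMVNHSQAWSTLTQDFLLQRKIGGDSKCGIREVCFDFEMQGLGAAPERHMDYFVRTSGALHFRIHPVKCCNWFGGPGL
>cathB_seed5
DELDCGTIFKKLNQEQYGLDSSLVQCVGGYPLFNDIYCSRWPYYVRTWTCTVSKWSFVDTDYWLWNEAHVWELKWNNPCYWTAHNQHFTLKIKIWGCLECRIREMMFHSYNQKPWPIPSRHDMYQVTLSVVWLNLKPGVKKDNLDIQPYI
>cathB_seed6
HELVNFTIEYKCNICITGGPYKLSCCFEFVFFFTTIGPFVWMYYIRTSTCQKSMWSYWTTDYWLSNEAHVISCSWTHIFRISLDMGVILLKDKIWYDYYAIIRHSMFIIEMQQITNRPSRHPMKDDDDAMVWLFRKHPVKVDNAASLPYL
>cathB_seed7
PELWCIDIDPRLNLSDTGDTTKLLRCEDFYFYLTDSGCARGCYYIITPTCGKAMWEVAYFRYTCHNMLIVCNLSWNYSMYTSIDNQHQALERPWWGDEKEIVREWMFHHGMQGITAFPSPHMMMFVPYSMQHLFRKHPVKKDNRTELPYL
>cathB_seed8
QELCCITIHEEFCECWVGQPAKLRQCGMFLFRFIDYGTSKTVYYTRTVLCMVIKWSKNYERELLGQKATVNLCDRNNSSYWSDDKSHFNTMIKIWGEQKARGRLRPHSNETWFIYAAKCRHLPYFVTLRLIKTFKKAPVKKPNCGFHPYL
>cathB_seed9
QSLACICGEKKLMISTRPDPAPLAQCEGFYFCPHDIGMSRFCVAINTPTCGSHNWSKEAVEYVLHNEQHHGALSWRNSSYWSADNQIFLMKNGIIGNKCCRIQPSMFHFEHQIISARVNRHCSGFVDASQVWLFLHHRVWKDNPDGKVYL
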