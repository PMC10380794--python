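>cathL_seed1
VGWFNHKCATFLSEESASRHNAGCRVQDVRQILMNMSKCQRKIKRCRECVMQPLPLSEAPRNFRGIECTYMEHCPAKILTLPGYHCAFARDPWCREDMQCRDDDVDYMFKFPVLEIANFTILPLANAVVEYMSWKYEHCLDKVSKNHFGKTISPVGMAMIEIPAATFRFLLVDEKGCQDCHTRPDSPNLWEGAYVTWVRNAPNSDFNCMY
>cathL_seed2
DTWFNRKWRTFLSIESYHRHNAGMRNIDGRPILRSMSCFLRWIPTCRELTDIPRPKSETPRLIRLFQSTYMEMCYAKILTYVGYACSWAVDPICRKDMDCSDDDFDNRFSFPWLWSAYFHILWIACNVVFYASWKLHHCSFEVCKNPNGKTNFYVTCTMWIIDTLTFRFLLVDVKGCQTSHQCPNGPNLWEGWYVTWGRNAMNSDFNNIR
>cathL_seed3
AGWCNTVCATHVDQRNASNHHNGSNVQDERQYRMNMSSETRAIRRCMVCVLQALPKVESFRNFRGTECTYFEHNPHKIWGLPYIHCAFAFFLWRREDMQHVKWDVDAQFKFPDDQINNFWRLWLANTVEEFMKWKNMHCLDEPCKRHFDKLHSPNCMAMIEPPLATFRVLLVHEKTCIQTHTIIHEWATRESFNVFWVRNTPNEDRNCMY
>cathL_seed4
VGPFYSHRTTHMSEEGTQTHNQGNRVQDVRVIQMNMSIYQRFIKRIRECVMQHVPLVECDCNMSGIETSYREHCPIKILLLMLMVCNFARTPWWYECMLCVDDDNLTMLKPLQTHHAKPTILAKCNAVGELMSLKFSHEKDPASKNHVGNRYSFLRMSIFEILAATFLFDLGKENGLQDDHTRPDKWQRWQGPFKKWGRIAPNSCSNICG
>cathL_seed5
VGWQFVDFVTEKSFFPVCRQNAGCRCQDGGTILMNMEKCEMMIARCRRTVQQQLHLSEAPLRHRGIEAHHAERCAAKIPTDGGYYCAFVDRHWCREDTSLRDGVVDYQCTEDVGWLADQTILIQANWSPVYMENKYEHCCDKVADNHDTWVAVPVWCWMIEYRYATETFTYVDESACQLCHTRTCSSYLWELAPMEHVRDAPNHCFGAMY
>cathL_seed6
VGATNEKCATFSSVDSEARDNNGCRYFDVWTHDMEMETCQRAIKTCHFQFMWCDGLSMCPLMFRWIECTYMEHCMFKILLQDEYHCAIAFDPVCREDMQTMHDIVDYMFKFPKWEEQNRENLPEANLCKEYIKPKYQHAADEVEKYHFYKFEHMCGRYHYNIPLASKDFLGVDEKGCQNCHCREYSYWLCEMAYIGMVRNIPNRDFSCMH
>cathL_seed7
SPWFNHMDALFHGGESASTHNAGNHVQMDRPIYLCMSRDKRKIKFGISEVYQWSCISEEPRAWNWITCTDWEWCPAYIAMLVGYHCAFKNDPKCRCDRQSRFDCIDGEFWFSVEEDAFTTILPLPPPLLEKVSWEYYHCLHHVSKEHEDKMISPVAMAFIEYMELTFVFLLVDEKKCYDCHLLNDSVNLWEGGCHYDVRKQPNSLFNVMY
>cathL_seed8
VFWINRKFATDWSQQSPERHNPTCRVNDMWNISCNEFKYQKKAKWCPPCDMQYLPLGEVYNLFRIEPYPYMSHTPRKQLTLPDYHCAFGRFRWQKECPHVRDDDVRYEWPNPVNECPNITILPLANRYVELMSWKYEHCYDKVSGMQASDTIIPPGVWAIAMPMYVQRFLLSTEKGCVDGHFIWKSINDSEGCYVYWVRDDRNSDDFWEY
>cathL_seed9
VGWFNWKCSTFSSEESASLHPVDCIVQIVRQIDMNFMKRQDKIKRRRGCVMQHQPGWEDPRCDKGWTCRYMPMCYAKQSTLPRYICAYANDHWVREDEQQGVKDLDWMNKTPVHELCNFTIHALAQAAVRTMSQKYDNCLGDVVKWHIINTISDDGKQMIFIPAAQFRNALVGEPVCIDCHARIDALALWLGEYFQWVPLLPNSMFRCAL
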