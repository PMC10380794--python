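>cathH_seed1
VGWFNHKCATFLSEESASRHNAGCRVQDVRQILMNMSKCQRKIKRCRECVMQPLPLSEAPTKAVHPTGTWHDGQKKFMRPVVHMCCIQHWGMHCDDVLREWDWEHYVHKNEFHIQHWDPNWPLTESRPDPGMMEFTHISIDQYRIKPILRMLLLCPCFPRWEGHCGSFFWTARHACQTMMHFWMAHDMRTLRVYEPWMELRINMQWYAHP
>cathH_seed2
CMQFNHKVDTFLSMECAHHHNTNCRSQHVRQQYYNQKSCQRKGKTCNPNYSQKLCPSQASTRAVHDTGTWFDGQKQFCRPVPLFACIQQWGLWCMDVLREHQGEHYVNKNEIHIQQTGTWARLTESRYDPGMYSFTHIKEYDYRCWDILNMKDDNPIFPLWGPAFGLMSWTWWQACQTMMHFWAFNVMSIPVKHEYWMERVSNMQSLAHP
>cathH_seed3
VGWFNHINITFSVEQGAPRHSAGKRVDDVMQMDKNRTKCQSKFKRYGEIVKYPRPLSCAPGDLVHYDDIWVDLNKMMMTFMVGMCCIAHEDRHFDDIPREWDARHYDHKNEFHIQGRDPNWILTESCPYIFMMNHSHPSTLQGKRSPILRMLLNGPYLPCWQSKCGSFEWCARYACQTMMHFWNAHLCWTRRSVEKWMEININDHWWVHR
>cathH_seed4
EGWFNHNCATFDIEISKIRHNAGMRVQFDCQALMMMIKCQRKWYECMGAVHQCLPRSEHWTKAWHPTGTWAKMRKKFMRPPYIMCCIQISVTWCDQVKRHWDWEHYVLKNKFSIHMWQPNWPSTEGRVDPSMMEFTHISIRQYRNKMMLRHWTLQECFWQKEFQCGQFFWTSIKMCIPKIHHWMAPDMDTARVYPWWMELAINFDWYAHP
>cathH_seed5
VHYFNDLCAEFSECFSYSIDHGFCRVQDVQQILFNRNKVWRKNERMRECVMHPGPAIGAHHKAVIPDGTCHSGQPKFERQVYHMCCIFHFGMKCYDDPKEWDWYHYVTWRQGHIQHWVPNPRLEVSRPSRQSKYKEHIFIKQYRDVHILQVRTLGVCRPEQEGHHGSCFDDARGMCRTMMHLKVAHHCQGRRVQEPWMVDRRNMQWYAHG
>cathH_seed6
PETFPPNQAMNLSWEQWECHNNGCAVGDVNMILRNTGKCPRFKKRCYENVMQPLPLSENPPNAVHDRQTYHDGQKKDERPVVHMCCTQVHGMHSDHILREPDWEHVVHVIEFWISHWDMNHEMTEQPPGRGPMEMTCIEIFQYSMKFLCEMHKLCQLEFRAEGHHGIFFWTRRHSCGTMVHFIMKWDMRTLRGYLPWMELRINMQWFVTP
>cathH_seed7
FGDFDHFCATALLECSLIRFWAMCRPQSVRQILMNMSPCGRPECRCRICVHQVLYLSMAEPKAHHPTGENHCGQAPFGLWVDEMHCKQHWVMHHDIALANWGKRVFVHKNNFHIQYWDEMWPLDEMRPDCGCVAFCHISPDQYEIGPILVMGLLTPHFPRWGHMCGSFFWVTRHACTTWLHFWMARHMRTLRCYRQEMELRINMQWYMHP
>cathH_seed8
VNWFNYKIGTFFCEESHSRKNAGCRCQQSRYIDDGSLKCQRKIKRCRKRVGEHLCLSEANKKTWMMQMTDHFGCTKAERCVVHVCCIRKWGMQTSDVLSEKDWHHFQHKAPEHHQHWMPNWPLTEARVGNGMMVFTHSSADQYKMKPHLRMFLWCAWFPRWEGGVGSFFWWARVFCQTMPHFEMAHYDGTRRVPEPPWICLINMQRYKYP
>cathH_seed9
QGWPAHKCCTACREESASRHNANCRQQDVCQYLMNMRYCDAWNCRARFCVGQPGRLADAQTFIGHEYMTKEDGSKKFMFWVWQMCCQSDWGMHCDDPLRFHLWRHGHHYNHCIIYHWDVWTPWRPRHPDSYVYEFTHHSNDNYRHKTILEMLLLCPCRPPWEVHCQSLFWPWQNADQTQMHCWATIMMRTLRSHEPWMPLRQNMQKYKHE
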