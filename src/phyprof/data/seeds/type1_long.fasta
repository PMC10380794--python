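>type1_long_seed1
LYGLNYMVIIHRIAYVVGPSKEAFGCRGFYLCSESVQKYWHFVTETQYSPLSDNPDKPRSRLEQDFRGHNMMRTVSMWRVMNGEMYHDYLRITEVTWLFVMGDQLVCFNLEFIAFQKLAVHPNSFGELGYNKLVEAYCCCSNNLWCQECWVNMLHNERADDSPDEMINMDVHPVIMIIESMMFIPCNMCERWLQHSNINDQKWSRFGRYFRVMSQNEEQHMRCKIQWWKTKEKLVIPDEYDNFDCCAMGDPGEICRNPYCKHMHIMMPEGNDEGLNTMQSRGEVVQMELWHVHLCNTSALITFEWVQDRMYHLNFCHAFVNCKWEYNWSQNYVFRMHGAPPSTQADGDPKQLSTMNRGDKGLSTLKPFHPNAQTVHRNMWHWTMIEYHMSCFHPYVKVTWQAFLRVMHSSFWGMPLSEPRNTTQCLQSLAHGIRETACICTQEIKFKPGYFAGYLVTVSVWEGMCMNAFTYKKFCKRKVDSHHHLMQQSYFADSFCMTANDHEFEHFHCFHAFHFHPEQIYWIALEICWDEGQKCGAVKLQKFYRLWQMTMTGPHSDRTGFNHYYSKGPHGVLDCQRR
>type1_long_seed2
HYGGAYMVEIIESASVVCPDTPFFGCKGSFLCWESVRKEWPLFTERNYAPQRIFPQKRRSQLCQWFRIHEMMRTGGMWRFAYWEMVQDILRTEEVTFQFVPGDQLGCENLEFIADGKNAMHPNSFGDIGYNGNVEMACCCSTNLWCQECWSNMRCNRQSDDSPDEMINTYVKPVTMDHISRSEIPPTKYEMEAQHSNRNDQIGSVFGRYFEVMSDWPEQHMPCNIKWRSVISKLSTWDTPLVFDCWADLMPQERARNPNWKHMHIKPRMGNDMQLTTGQSTKEVWFMELTHQKLRNSAAWTTFLGVLIREYHVWFNHRNTNCKAFYYQSQNYYFTEHGAPPSHYADIDSKQYSCRWRHDKGLDTKKPEGPNAQTFKCNGYEEPMIENAIRCVHPYVKITKQYFLREMHISFWTMPLSEPHDLIWKLISTWHQIRRTACSRTQFIKDSTSYFKGELVPVQVWINMHGCAAAMKCFCFRKLIYHHTKIEQSYFATSFCWTANDSEFEHHHLFTAVHFTQEQVVHDHLFICWDEGDKPGAVKLQNFYSLWQMTPTGSHSICLGLNHYYSHGHHLALDCGTP
>type1_long_seed3
LDGRNPMVPIHWIAEMQGISIEAFKCPVFDECSEMHQQYNHWVTQTEAKPISENPDWERSMCEETFRGHGMWRTVSCWRHRNAKLGPNYLHIFFQFWDFMMGENLVPRLTDFIAFQALAVHPNSIQELRYNAHYCASICICVNLWHDECWIEPLGVEKAFWMPGEMINMDVHPVDMLISTMQFLPSNMCERELQDSRITDQVPWLFGRIFSVWSQNGEQEMRCKIQWWKTKEHPRISQMTDNFDSQDCGDPREIDYNPYCKHMRIMNWEGNDEGLMTMQVRGHVNQMYYPTMHLMNTMPLITFKQVQSRMYHFSFHWASVNCDFEINWDQHPEFVFHGAPLTTQADGDPELVSNGVRGPYEWWTRKPFHMNYSTEHDNVDEWFMIEYHHSCHHTNTQVTWCRQYRVCGSGFITMPLSPDRNYTQYYEFCANGIYELWCVCQVERKFKPSLFAGMLVTGSSYEHYQNNAFEYKMFCKRRQCFNHHLVWPSSVDRFFYKTARFIEGCHLSCFSAWHWRVMQIYWVTLEICTDHCAKCLYVPPHKFYYLWQMTMWGMHIDRTRFNWFYVNGGPGIYDCQRL
>type1_long_seed4
FYGLNYMVIFRRIAYPVLPWKDAFGCRGFYKHVNQVQIYQHFKNETWYSKCSEWPDLPRARDKQTFIGHDMMCTLSMARWMRWQMYKQYQFKNMVVILFDMQDFLVHFHLTYISFQPGANHWRSVFALEYLKLGEEYCCCSNNLTCQECLVVELWNSRVDRSPEEMMHIDTVHEIMCIENMMFITCNMCDRWLCHWEINDQKWLRDGRYFIVNSQNDEQHMRKKIMWWKHKEVAVIPFCYDNFDMWIMGTYGESRMNFYCKHMHIMDPEGNNSGLNECSYTGEVVQMEKWHHHLCNTCGRYWFVWVRDRKYHPNTCHKFVLCKFWQNWDDMAESDQHTAPPSTQADRWPKWLSTMNRGEKGDSIDIIWEPKCLAEHGNMPHHPMLWGGGSCFNRYPGVTLQASLRTFHSQQRGMPGSDPRNTTQCVQSLYHHWRETTCICTQQWVAKPGYTAGALVTMSSWEIVCMTAFHYKHTCKYIVDSHHHLMEGSTFADLICMNANDHDVYHFHPFHAFHLHMEVKYKFPLEICIDENSHCGARKLQSFYKLWDMTTTGPHSDVIGFNCYHVCGMHEDLDWTNE
>type1_long_seed5
LYGDNMMVMIQRIPYWSSHMKEVFTCRAFYLCSESVQYATHIVTEQRYSPAISMNNFPWSALEQDVRCINMMRTPCEWRTMNGTPMHDYLRIKEVKWLVVTLKQMSWFALIFIASQKMAFHPLSFGELGYYCQVEAYPPVENNLGCQACKVNMLHYERAHDSPDMMYNCDVHPWFMIVENMMYQFMKTCERWLPHGTINWNKISRDGRTFCWGSCNEEQHMRHSCQMMKTQERLVYPVEYLNFYHLYWGDPGEIERVPQSYSMNIQMVMHNDEGLNVMQSRVRVNQMELGKPHCPAQSAPITPVVMQPRMNHLNICHATLGVHCEMNVAQNYACFMRGKMPSTQMDIDPKNLPAFNMHDKILSTLKGFHPNAQTVFEPMWHWTQIFYHMWCWHKYVYVTPMAHLKEMHSSFWGKGNDRPMNTTQKAQSDQLGEREWACRYYQEYKFPPYYVYGDLVTTSVREGAAMWFFTYPKECKCKVVSHGHLNQESYFQDIFCMTAIKMQFEANYCICAFDRMFEQIHWVAYEICGDPGQHCGKIAKQKFYRYWHQTNTTYHQYATGFNLYFCKCLNWCLNCQRF
>type1_long_seed6
YYGLNYMVHMSRGMHVFEPSKMVFFCDIFYQCSECFGEYWHFVTETCYSPLIDNCDPPYVRREVDFAGPEMMRTHSGHRHDNGEYYHHYPRITEGIKLFPMGDNIVCINLEQYMFSDFVVHMIKFPNLGSVKLCEAYACCSNNLWFTRCWVLGCCNERDDLMTHFMWWEDFHPVIEWIMSMMFPQPCMYERNLQTSNIWSQKWCHFYSYLRVWSQNVYSHMRCKIQKWGTHGKLVIPDGYDNFIDGNGGNPGIIPHNFYCGHKVIKAFVGNPCGARAMQRRGEVVNMERWHVHLQFTMYMIYFEWQQNYDYHDNCCHNIVNCELQGNKSMNSGWRMDRYPGFKVADGDMWAQSCDFCLDKGAPTLKPEFPLAQQVHKNPWHWTMQQHHISCFHPYVRVQWQAKMRYAHSSSWEMIESAPRNTTQDSQILAHGICETACICTQEHPFQPHYVAGSLSTVSRWFKMIKNHETPVKWEVMKVDSPGDYQQMMQFADSKCMTLKDPCDEHFHCFHAFYIHPEQIYQFALAIAFDSGQKGDAVNLQMMYRLCDMTRTVPKSDGTGFNVQWSKKPKGADCVQYN
>type1_long_seed7
LLGLAYMVPMGGIAEVFLSHKGAIGCPRFYLYSHSVEWYAPHAAEMVYSEGIDNPLPSKVRQFQDFLSHNRMRAVSTCHHLIDGALHDCLRDTEAWVQTPMGMQGVHFNGEFGARQKLVDHVDSFGSLGYNKVMEFYCQCKNNPWINEIKYNISHNDRSNGSPYTMENMIVKPVIDLCEGIMPSPCTMCVATGEVSNLNDVKPMRCGRYNRAMSQNGQQPMTCKSCHWKTTEMEVKWDFYDNFDCKASGQPQETCMQAYCDKWHEKTPECNDLGLNTMLSENHVVPMNLWFVHLCNLGILIIFEWVQDRMYHLWFCQAFQDSNKSSNNSQEDTNRMHWWPPFTGAFGDNRKLSTTNRRDKGFSNLCDFRVWRQHVCLEFMHCHNLEYFMFFFHNKVCPTWSAMDLVMTSQFNQMTLSENLNHIHCNQSLIHEFFEAADICTQPIKFTQGYHEGQAVTNYRWEGMCVNELTWRDFPKRIVKKLHHLMQQSYFACWKCMTAADHWFEHFSCWHASHLHPFFIVTIWMMWCWDELQKKLKVHLQKWRVLWMMTKTGSHSDRIGNLHYYWNGAKLVSDCQKR
>type1_long_seed8
LYGLNIMGVIKGIALFVGPSQEATGCRDFYLCSYRACQYMHFLTHTKEFPLSDIPKKPRTRLWERRRARNMSFEVSMDWDIAASMYHNYLRITLVIFLHEMRDQLWVKNLYCDAFWSLATHPNSPGECKGNKGGLAACCCLENLHKQECNVSMDHNELDDLREDFMINPDVWPVIMIIESMMSIPKNFCMARLQHLNENCQQLIRWGVYFRVMRSNAFQYIRCDISDWNQPEKDNIPMQKVTGKCLMEPCPGEICRIPYAKDPHILMPSGDDEGLNTLGGRGEVKDMELAAIHLCGTSQLITFEWVVCRMWLLNFSHARVNGKLEYRWPQNQCFQLSGWNPSVQTDGPIKQTNYMLRIDVGLSTLAPFHCPAQTMHRNMWGVPMIYYHMHCVHPKVFVTWQNFNRVMHSSFWMMTPNEPRNITECLASLAAGILETTAEWTEEIKNAPGIFAVGLFTIKVWEGQCRIMFYWKKFCDRHVDSSQALMCQHGFAISICTDANRHEVEHFHKKLAMHFHPDQDYWIALEICWDEMQKCGLVKVQSCERLMEMTKTGPLWCYFGFVHYYPKGSAGVLDMDQE
>type1_long_seed9
LYAQNYDVYWPRITYVGGPSEEVYGCRGKAGCGVSGQKVWHSVTETQYSNKCDNADEDDSRLEQTHQIHNEMPKVSMWRVHAQEMLHDCLRPNYVTAAFVMFDQLVQFNLKFWGNQDAAVHPWQFQPRFYNELVEAYMCCNNNDWCQWCVANMLRDKCTDDSPFEGFNMDVHPVLRGNESTMPRPCETCEFLEMHGNWPSQNWSRLNRYRFSMCQSAEQANRCKINVWKPKEKLWPPKPRFKMDCCAFGDVGPICPLPYCTHVDIAMPNSMDEAENCMQARGESHQYEKWHVHLMDTSAAMVFEESWDRMELTNFHHAFWRCKWPYIWSQNAVFGRHGIPPSTDADPDMKQLSTMNMWDKGLSGVKPFHPKAQTVHRGMPHWTFLEQHMICFAPYRKLLLPAFLRVWHSSPWKWPLTEVRDIQQCTQSFAHYIMEYACITTPQMAPKPGYFAAYFVTHFVWDTMGMNLFTCKKSKVLKWDSMHHLMMQFWEADKRCMEAADHEFMNAVCYHYFHPHIWKIYSHPLEMCDRSGQQCGAVFWQKFNRIWQMHMDMPHNLRTGKNHLFSKYEYGWLDMIMD
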