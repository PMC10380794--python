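>cathO_seed1
ESYLGFGTVVMTYRVGFCDIAVCNSCYVCTCTFDDTWCICWMKCNCSEIWSTDICLSCAYCNGFFQDTRRKSENQMNMKGDFVFTRTIANEKDHNEQFDEVMEQMAVSFSQETIDLPWPWHSAAVFPHVQIRSNHVDKHQMINCRDNPKH
>cathO_seed2
EDYLGVFIDVGTYALGFCDIAQEMNCQVCLCTFDSTCCVCWMKSMCSECHSTDICLICAPCNGMCQDKRRFMENLMNLKGDYVEGPAIANMKDHLEQFIGVMNNMARSFNTETRKMPSEWHSAAKCAKTQIKANCQDGHLTANCRDRPKH
>cathO_seed3
FSYLMFYTYVWTFLLKFQDQPVCFWCYEGTMAFVRHWCIYWMKVNAHENWNTDICKVCVHCAGEPRDTRRMSINQMNMRGWGVVTRNIQYEYDHLEAFDEVMEQMCYMFSQTTRDLPSAWHSPPNYPHVFIRSNHPDCEQSRNCTMNPIK
>cathO_seed4
RPVLQFITAVMTYRVCFPCNAVCNACYSGECTFDDVWCSCWKRQNQHEVWHTDGTYVCAYVNGFWQQTRYKSEHQMNMHGDFVFFEYCDLWMWHNCQFDEVMKEMEASEIVDTEDLIWPWHMAEVFDHVQIRMNYVDPHEMINCKHGPKH
>cathO_seed5
EDSFWFGTDQMRYRVELDDIAITNDCYVCGCTPMTTSCWCWVWCSCWELWDTDNCVSCLGIIGFRSDERRKSEKQMNLPGWVVETRTIANEKDINSGFDEVMNYTAKSFSQEEHDGPDPWHAAEVFFHVQPPSYHEGKHEMFNVWDDLKM
>cathO_seed6
MYQLGFHTIVWTYGVGFCGIAAVCHCKPYQCTFDQTWCICWMNCNCSEIWCTNRPGMCIYCNCKFQFTRRYVANGMNMKDDFFFHRTLKIPKMHNEQFDFVMEDMAVQFCQHYIQWPWPHHSAAPFYSAQDVGNHMDKHQMRNCFDNHCH
>cathO_seed7
VTWLGAGIVCNTYIDVPSDIAVEGSCYMNTTSFDDTWCICWMKCRRSEGQYTNICLKCAYCTLFCQITIMLMENQYSMYGDFYFVRTWAPEIDHIERRIEVMCQIAQSFSQESIDLPWPWHSAKVKDHFQILSNHVDKMNGMNCRDEPKH
>cathO_seed8
EVMRWIGTEVMTYRVGHYPAAVCISCYECTCTFDDSACDCQMKCICSIIWTTAVCMSCAGYNGFMQWTPRKSEDENNMGGNTMFHHTIAIENYHQTFEDEVMEVRQVSFSQELITQPWFWHGAFQFPAVCISSNHVKEHNMQNCFGNLIH
>cathO_seed9
DSYLGFGWVVHTLRQGFQDFPVPNSCYRSTCTFDDTWVKPDAKCVGTIIWSEDWLTSIAICFLFGQSTRRKHCWSRNNIGRTVGTESLAWERDVNRQFPMRSVQMAVSLSQETIGMPWKYHSASVLPRNPRSMNFVDKHDMCNCRDNPKE
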