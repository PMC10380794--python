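>vWFA_C1_seed1
TNPPKYMHYTQDDDDATYIGNTFHYCRLYPISHVMNQMNNFIWEIPTLCKGCAKLFCIMISCAEHYWVKKICGLIMHRCLHHGFYHIMNCMYMGRRVGTNPLANEQISQNFMSNMRYAECHCVGPFCQPFPGCKHPCWGFWSNARSSYPY
>vWFA_C1_seed2
TNAITGMDHTNVTDDATPTGWTGTGCVLYPISHVMQQMEEFIPEHPKLCKFCAKLECHHITKEEWYWFKKIAQGIMGVCLPLGFYHILNLGWSGRRVATNPQANEQQMQVFMSPSRLKFCHCVAPCCWTFNGHRSCQQKNWSNRRLSYPC
>vWFA_C1_seed3
TNPPKCMHVFVDCLWIWSMGRTFHYCSLYGITHVMHKIQNFHWFIPTLCKGCAKTFNCMKNDAVCYNEKKFCLLHKARCFHLLQYHIFNQMYMKRRVGTNPLANEQRSQFFMSYALFEEHHWVGTFEFPFYGCKTPCWHSDSNARRSYEY
>vWFA_C1_seed4
TNPPKYPHCTADDFDQTYRLVTFHMCRTYCARHVMCLHNNFIWEIPTLCKADACLWLILISCGSPYFVKWLCRLIPHLCLHHFFCHIMNSMCMGERVGCNFLKLEQISQNESSIDRYQSCHMVGPECQLECVCTHPCAGFWSNCRSHYDY
>vWFA_C1_seed5
IRPQKYMHYTQPDFCIIYKCWGQHMCIHCPISVEVNYGNNFIWEAPQLTAGCVSLKCIEIFCVYEHWVPKICHYIDKPCFHHGFYHYWGMMNMVNRVDTNVLANYQISQFFFSNKRYRMCHSVGCFCHPVPGCKQICWGFMSNDRSDAPD
>vWFA_C1_seed6
TIPYKYMHYMQDKDDAQYIGNTMHYCDRYPICHVMNQMNNFCWEIPTLSWGCCLFFCCMIRCAEHYWVLKKGGLEMHRKLTQGVVHIENMMYWGPFHGSNYMANTRFSCNFMSNMRYFTCHWVGYFYQWFPECYHPCCGFLYNARYNYPY
>vWFA_C1_seed7
RNPPKPMHDKHMFRDATYIGNTRHYCDLYPISREMNCNNRFIWAPYNLCKGQSKLFKTMAQCPEHYWVHKICGPWMHAEDSFGGYHIMNCMYMGWREDTNPLANEQSSQDFYSNMRYAEEHCETEICTAFHGSKHFTYYNISNTVLSYGR
>vWFA_C1_seed8
FGPYHYHVYTQDDDSWRDIGVQHHYCRCYRIRRVSNQGLKFHWRNPPPFGWCKKLDCIMISCYRMKGRKKICGCIMLHEISHGYIHIMNCMYDERRVGHNYLANENQHDNWDSMWLYALKHCVWSNYGPMPGWKHPCTGYWSNARSSNAN
>vWFA_C1_seed9
ANPRKYLGEMQDRDHATYFENWCWVCRLYGISHVMVQMKRSIWEKPTLCWWIAEGFMPMIKCMETYDVKKIYVLNTHLCAHHGTYNSVNFMYMFRYTHTCSEANEMPVQRFMWCLRANVVHCNVPFIVRFAGNKDPCHKFPSNADSSNGD
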