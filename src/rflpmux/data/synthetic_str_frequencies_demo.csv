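locus,allele,frequency
FGA,17,0.005
FGA,18,0.02
FGA,19,0.055
FGA,20,0.095
FGA,21,0.17
FGA,22,0.19
FGA,22.2,0.01
FGA,23,0.15
FGA,24,0.14
FGA,25,0.09
FGA,26,0.04
FGA,27,0.02
FGA,28,0.01
FGA,29,0.003
FGA,30,0.002
SE33,13,0.005
SE33,14,0.02
SE33,15,0.03
SE33,16,0.045
SE33,17,0.065
SE33,18,0.075
SE33,19,0.08
SE33,20,0.065
SE33,20.2,0.025
SE33,21,0.05
SE33,21.2,0.03
SE33,22.2,0.04
SE33,23.2,0.045
SE33,24.2,0.04
SE33,25.2,0.055
SE33,26.2,0.07
SE33,27.2,0.075
SE33,28.2,0.08
SE33,29.2,0.06
SE33,30.2,0.03
SE33,31.2,0.01
SE33,33.2,0.003
SE33,34.2,0.002
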