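# Genomic grade index, representative proliferation-module subset
AURKA
BUB1B
CCNA2
CDC2
CDC20
CENPA
CENPE
FOXM1
KIF11
KIF14
KPNA2
MCM2
MELK
MYBL2
PLK1
PRC1
RRM2
TOP2A
TPX2
UBE2C
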