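# EndoPredict 12-gene panel (8 genes of interest + normalization genes)
BIRC5
UBE2C
DHCR7
RBBP8
IL6ST
AZGP1
MGP
STC2
CALM2
OAZ1
RPL37A
CASC3
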