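# Placeholder for a reported 26-gene proliferation signature; edit to taste.
AURKA
BIRC5
BUB1
CCNB2
CDK1
CDKN3
CENPF
CKS2
DLGAP5
FOXM1
HMMR
KIF20A
KIF2C
MAD2L1
MCM10
MELK
NDC80
NUSAP1
PBK
PLK1
PTTG1
RACGAP1
RRM2
TPX2
TTK
UBE2C
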