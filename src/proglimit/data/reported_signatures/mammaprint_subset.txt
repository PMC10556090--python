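# MammaPrint 70-gene signature, representative subset
ALDH4A1
BBC3
CCNE2
CDC42BPA
CENPA
DIAPH3
ECT2
ESM1
FLT1
GMPS
GNAZ
GPR180
HRASLS
IGFBP5
MCM6
MELK
MMP9
MTDH
NUSAP1
ORC6
OXCT1
PITRM1
PRC1
RFC4
RUNDC1
SCUBE2
STK32B
TGFB3
WISP1
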