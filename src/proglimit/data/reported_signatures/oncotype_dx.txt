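# Oncotype DX 21-gene recurrence score panel (16 cancer-related + 5 reference genes)
MKI67
AURKA
BIRC5
CCNB1
MYBL2
MMP11
CTSV
GRB7
ERBB2
ESR1
PGR
BCL2
SCUBE2
GSTM1
CD68
BAG1
ACTB
GAPDH
RPLP0
GUSB
TFRC
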