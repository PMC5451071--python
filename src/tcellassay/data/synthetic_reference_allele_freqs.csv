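locus,allele,frequency
DRB1,*01:01,0.090
DRB1,*01:02,0.015
DRB1,*03:01,0.110
DRB1,*04:01,0.080
DRB1,*04:04,0.035
DRB1,*07:01,0.130
DRB1,*08:01,0.030
DRB1,*10:01,0.010
DRB1,*11:01,0.060
DRB1,*12:01,0.020
DRB1,*13:01,0.060
DRB1,*13:02,0.040
DRB1,*14:01,0.025
DRB1,*15:01,0.140
DRB1,*16:01,0.020
DRB1,OTHER,0.135
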