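sample,total
S1,27.68
S2,12.38
S3,19.91
S4,13.41
S5,19.03
S6,20.72
S7,21.58
S8,25.44
S9,23.44
S10,21.36
S11,41.15
S12,25.32
S13,21.04
S14,20.59
S15,32.98
S16,17.15
S17,23.01
S18,26.54
S19,5.76
S20,3.52
S21,12.75
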