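sample,material,producing_area
S1,G. elata tubers,"Zhaotong, Yunnan, China"
S2,G. elata tubers,"Zhaotong, Yunnan, China"
S3,G. elata tubers,"Zhaotong, Yunnan, China"
S4,G. elata tubers,"Zhaotong, Yunnan, China"
S5,G. elata tubers,"Zhaotong, Yunnan, China"
S6,G. elata tubers,"Zhaotong, Yunnan, China"
S7,G. elata tubers,"Lijiang, Yunnan, China"
S8,G. elata tubers,"Bijie, Guizhou, China"
S9,G. elata tubers,"Zhengyuan, Guizhou, China"
S10,G. elata tubers,"Qiandongnan, Guizhou, China"
S11,G. elata tubers,"Bijie, Guizhou, China"
S12,G. elata tubers,"Enshi, Hubei, China"
S13,G. elata tubers,"Yichang, Hubei, China"
S14,G. elata tubers,"Hanzhong, Shanxi, China"
S15,G. elata tubers,"Qinling, Shanxi, China"
S16,G. elata tubers,"Qinchuan, Sichuang, China"
S17,G. elata tubers,"Longnan, Gansu, China"
S18,G. elata tubers,"Anhui, China"
S19,G. elata tubers,"Moju, South Korea"
S20,G. elata tubers,"Chun chuan, South Korea"
S21,G. elata tuber slices,"Yingyang, South Korea"
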