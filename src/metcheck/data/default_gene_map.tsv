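gene	enzyme	rate_key
HK1	HK	k_R1
HK2	HK	k_R1
HK3	HK	k_R1
G6PD	G6PD	k_R2
GPI	GLYC_LOW	k_R3
PFKL	GLYC_LOW	k_R3
PFKM	GLYC_LOW	k_R3
GAPDH	GLYC_LOW	k_R3
PKM	GLYC_LOW	k_R3
LDHA	LDH	k_R4
LDHB	LDH	k_R4
PDHA1	PDH	k_R5
PDHB	PDH	k_R5
FASN	FASN	k_R6
CS	CS	k_R7
ACO2	ACO_IDH	k_R8
IDH1	ACO_IDH	k_R8
IDH2	ACO_IDH	k_R8
OGDH	TCA_OX	k_R9
SDHA	TCA_OX	k_R9
FH	TCA_OX	k_R9
MDH2	MDH	k_R10
ME1	ME	k_R11
ME2	ME	k_R11
GLS	GLNLYSIS	k_R12
GLUD1	GLNLYSIS	k_R12
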