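# 22 kinase hits of the kinome-wide EROD screen (>=2-of-3 concordance)
ITPKA
PMVK
PNCK
AK3
BMPR2
CCT2
COASY
HIPK1
IPMK
LMTK2
LMTK3
MPP6
MYO3A
NRK
PIK3C2G
PIM2
PRPF4B
SBK1
SNF1LK2
SPHK1
TRIB2
UCK1
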