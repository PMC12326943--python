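# Default p53 transcriptional target panel (59 genes).
# Curated from well-established, directly p53-regulated genes spanning cell-cycle
# arrest, apoptosis, DNA repair, metabolism and feedback regulation. This file is
# a plain editable configuration: replace it with any study-specific panel
# (one gene symbol per line, '#' for comments).
CDKN1A
MDM2
BAX
BBC3
PMAIP1
TP53I3
GADD45A
SFN
SERPINB5
TNFRSF10B
FAS
APAF1
PERP
SIAH1
EI24
RRM2B
SESN1
SESN2
DDB2
XPC
POLH
RPRM
ZMAT3
BTG2
PLK3
PTEN
IGFBP3
SERPINE1
THBS1
CX3CL1
ICAM1
TNFRSF10A
CASP6
TP53AIP1
AEN
FDXR
TIGAR
DRAM1
PIDD1
TRIAP1
GDF15
TP53INP1
CCNG1
CCNK
PCNA
GTSE1
PLK2
PRODH
STEAP3
FUCA1
DKK1
MDM4
TRAF4
ACER2
SULF2
NINJ1
RGS16
EPHA2
TP53TG1
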