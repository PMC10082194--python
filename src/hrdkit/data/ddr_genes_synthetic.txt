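# Synthetic placeholder for a DNA-damage-response gene list (the study
# design assembles it from GO annotations, which needs a live ontology
# query).  This is a small curated subset of canonical DDR genes covering
# checkpoint, repair, replication, translesion synthesis and telomere
# maintenance.  Replace with a full list (one symbol per line) for real
# analyses.
ATM
ATR
ATRIP
BARD1
BLM
BRCA1
BRCA2
BRIP1
CDC25A
CDK12
CHEK1
CHEK2
ERCC1
ERCC2
ERCC4
EXO1
FANCA
FANCB
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCI
FANCL
FANCM
FEN1
GEN1
LIG1
LIG4
MCM2
MCM3
MCM4
MCM5
MCM6
MCM7
MDC1
MLH1
MRE11
MSH2
MSH3
MSH6
MUS81
NBN
ORC1
ORC2
ORC3
ORC4
ORC5
ORC6
PALB2
PARP1
PARP2
PCNA
POLB
POLD1
POLE
POLH
POLK
POLQ
PRKDC
RAD1
RAD17
RAD18
RAD21
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RAD52
RAD54L
REV1
REV3L
RPA1
RPA2
RPA3
SLX4
TERF1
TERF2
TERT
TONSL
TOPBP1
TP53BP1
WRN
XPA
XPC
XRCC1
XRCC2
XRCC3
XRCC4
XRCC5
XRCC6
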