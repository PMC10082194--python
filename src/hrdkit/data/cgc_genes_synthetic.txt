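# Synthetic placeholder for a cancer gene census symbol list.
# The licensed census cannot be redistributed; this is a small curated
# subset of widely known cancer genes for testing and demonstration.
# Replace with a full list (one symbol per line) for real analyses.
AKT1
APC
ARID1A
ATM
ATR
BAP1
BARD1
BRAF
BRCA1
BRCA2
BRIP1
CCND1
CDH1
CDK12
CDK4
CDKN2A
CHEK2
CREBBP
CTNNB1
EGFR
ERBB2
ERCC2
EZH2
FANCA
FANCC
FANCD2
FBXW7
FGFR2
GATA3
HRAS
IDH1
KIT
KMT2C
KMT2D
KRAS
MAP3K1
MLH1
MSH2
MSH6
MYC
NBN
NF1
NOTCH1
NRAS
ORC1
PALB2
PBRM1
PIK3CA
PIK3R1
PTEN
RAD21
RAD51B
RB1
RET
SETD2
SMAD4
SMARCA4
STK11
TP53
VHL
XRCC2
XRCC3
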