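# Synthetic stand-in CHIP gene panel (78 symbols) assembled from canonical
# CHIP / myeloid-driver gene lists; replace with your own panel file for
# real analyses.  One symbol per line.
DNMT3A
TET2
ASXL1
JAK2
SF3B1
SRSF2
U2AF1
U2AF2
ZRSR2
TP53
PPM1D
CBL
GNB1
GNAS
BCOR
BCORL1
CREBBP
CUX1
KDM6A
MPL
CALR
FLT3
NRAS
KRAS
IDH1
IDH2
RUNX1
NF1
EZH2
RAD21
STAG2
SMC1A
SMC3
PHF6
KMT2A
KMT2D
KIT
NPM1
CEBPA
ETV6
WT1
GATA2
GATA3
PTPN11
SETBP1
SETD2
ASXL2
BRAF
CSF1R
CSF3R
DDX41
DNMT1
EED
EP300
FBXW7
IKZF1
JAK1
JAK3
KDM5C
LUC7L2
MYD88
NOTCH1
NOTCH2
PDS5B
PIGA
PRPF40B
PRPF8
PTEN
RB1
SH2B3
SRCAP
STAT3
SUZ12
TERT
YLPM1
ZBTB33
CTCF
MGA
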