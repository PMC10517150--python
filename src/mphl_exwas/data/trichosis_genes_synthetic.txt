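# Synthetic stand-in list of 65 monogenic trichosis (inherited hair
# disorder) gene symbols, for enrichment testing.  Assembled from genes
# publicly associated with hypotrichoses, ectodermal dysplasias and
# related hair phenotypes; NOT the curated 65-gene list of any specific
# study.
WNT10A
HOXC13
DSP
LPAR6
ALX4
EDAR
CDH3
HR
SPINK5
EDA
EDARADD
WNT10B
KRT25
KRT71
KRT74
KRT85
KRT86
KRT81
KRT83
LIPH
DSG4
DSC3
TGM3
FOXN1
GJB6
TP63
IKBKG
NECTIN1
NECTIN4
PKP1
JUP
DSG1
KRT14
KRT5
TWIST2
RIPK4
IRF6
CDSN
APCDD1
RPL21
SNRPE
LSS
C3ORF52
DCAF17
VPS41
EPS8L3
KRT16
KRT17
PADI3
TGM1
ST14
CST6
SGPL1
CERS3
ELOVL4
ABHD5
NSDHL
EBP
MBTPS2
PORCN
ATP7A
FGFR2
FGF5
TSPEAR
GRHL2
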