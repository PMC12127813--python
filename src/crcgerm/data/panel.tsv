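symbol	category	penetrance
AIP	diagnostic	unknown
EGFR	diagnostic	unknown
NF2	diagnostic	unknown
RUNX1	diagnostic	unknown
ALK	diagnostic	unknown
EPCAM	diagnostic	unknown
NOTCH2	diagnostic	unknown
SDHA	diagnostic	unknown
APC	diagnostic	unknown
EPM2A	diagnostic	unknown
NOTCH3	diagnostic	less_well_defined
SDHAF2	diagnostic	unknown
ATM	diagnostic	unknown
FAN1	diagnostic	unknown
NRAS	diagnostic	unknown
SDHB	diagnostic	unknown
AXIN2	diagnostic	unknown
FH	diagnostic	unknown
NTHL1	diagnostic	less_well_defined
SDHC	diagnostic	unknown
BAP1	diagnostic	unknown
FLCN	diagnostic	less_well_defined
PALB2	diagnostic	unknown
SDHD	diagnostic	unknown
BARD1	diagnostic	moderate
GALNT12	diagnostic	unknown
PDGFRA	diagnostic	unknown
SMAD4	diagnostic	unknown
BLM	diagnostic	unknown
GATA2	diagnostic	unknown
PHOX2B	diagnostic	unknown
SMARCA4	diagnostic	unknown
BMPR1A	diagnostic	high
GPC3	diagnostic	unknown
PIF1	diagnostic	unknown
SMARCB1	diagnostic	unknown
BRAF	diagnostic	unknown
GREM1	diagnostic	unknown
PIK3CA	diagnostic	unknown
SMARCE1	diagnostic	unknown
BRCA1	diagnostic	unknown
HOXB13	diagnostic	unknown
PMS1	diagnostic	unknown
STK11	diagnostic	unknown
BRCA2	diagnostic	unknown
HRAS	diagnostic	unknown
PMS2	diagnostic	unknown
SUFU	diagnostic	unknown
BRIP1	diagnostic	unknown
KIT	diagnostic	unknown
POLD1	diagnostic	unknown
TELO2	diagnostic	unknown
CASR	diagnostic	unknown
KRAS	diagnostic	unknown
POLE	diagnostic	unknown
TERC	diagnostic	unknown
CCND1	diagnostic	unknown
MAX	diagnostic	unknown
POT1	diagnostic	unknown
TERT	diagnostic	unknown
CDC73	diagnostic	unknown
MEN1	diagnostic	unknown
PRKAR1A	diagnostic	unknown
TGFBR2	diagnostic	unknown
CDH1	diagnostic	unknown
MET	diagnostic	unknown
PTCH1	diagnostic	high
TMEM127	diagnostic	unknown
CDK4	diagnostic	unknown
MITF	diagnostic	unknown
PTEN	diagnostic	unknown
TP53	diagnostic	unknown
CDKN1B	diagnostic	unknown
MLH1	diagnostic	high
RAD50	diagnostic	unknown
TSC1	diagnostic	unknown
CDKN1C	diagnostic	unknown
MLH3	diagnostic	unknown
RAD51C	diagnostic	unknown
TSC2	diagnostic	unknown
CDKN2A	diagnostic	unknown
MSH2	diagnostic	unknown
RAD51D	diagnostic	unknown
VHL	diagnostic	unknown
CEBPA	diagnostic	unknown
MSH3	diagnostic	unknown
RB1	diagnostic	unknown
WRN	diagnostic	unknown
CHEK2	diagnostic	unknown
MSH6	diagnostic	high
RBL1	diagnostic	unknown
WT1	diagnostic	unknown
CTNNA1	diagnostic	unknown
MUTYH	diagnostic	unknown
RECQL4	diagnostic	unknown
XAF1	diagnostic	unknown
DICER1	diagnostic	unknown
NBN	diagnostic	unknown
RET	diagnostic	unknown
DIS3L2	diagnostic	unknown
NF1	diagnostic	unknown
RNF43	diagnostic	unknown
ACTR1B	candidate	unknown
EDN1	candidate	unknown
MAMSTR	candidate	unknown
SBF2	candidate	unknown
ALCAM	candidate	unknown
EIF3H	candidate	unknown
MGMT	candidate	unknown
SEMA4A	candidate	unknown
APE1	candidate	unknown
ERCC1	candidate	less_well_defined
MRE11	candidate	unknown
SF3A3	candidate	unknown
ARFGEF2	candidate	unknown
EXO1	candidate	less_well_defined
MRE11A	candidate	unknown
SFMBT1	candidate	unknown
ATF1	candidate	unknown
FAM109A	candidate	unknown
MYC	candidate	unknown
SH2B3	candidate	unknown
ATXN2	candidate	unknown
FANCC	candidate	unknown
MYO3A	candidate	unknown
SHROOM2	candidate	unknown
B9D2	candidate	unknown
FANCE	candidate	unknown
NABP1	candidate	unknown
SLC15A4	candidate	unknown
BMP2	candidate	unknown
FEN1	candidate	unknown
NCAPG	candidate	unknown
SLC6A18	candidate	unknown
BMP4	candidate	unknown
FKBP5	candidate	unknown
NXN	candidate	unknown
SMAD6	candidate	unknown
BMP5	candidate	unknown
FMN1	candidate	unknown
OGG1	candidate	less_well_defined
SMAD7	candidate	unknown
BORA	candidate	unknown
FUT2	candidate	unknown
PIAS1	candidate	unknown
SMAD9	candidate	less_well_defined
C11orf53	candidate	unknown
GLI3	candidate	unknown
PITX1	candidate	unknown
SMARCD1	candidate	unknown
CABLES2	candidate	unknown
GNL1	candidate	unknown
PLCB1	candidate	unknown
TBX3	candidate	unknown
CCND2	candidate	unknown
HHIP	candidate	unknown
PLGLA	candidate	unknown
TCF7L2	candidate	unknown
CD44	candidate	unknown
HNF4A	candidate	unknown
PNKD	candidate	unknown
TFEB	candidate	unknown
CDKN2B	candidate	unknown
IL12RB1	candidate	less_well_defined
POLD3	candidate	unknown
TLE4	candidate	unknown
CHRDL2	candidate	unknown
KDR	candidate	unknown
POU5F1B	candidate	unknown
TMBIM1	candidate	unknown
COL4A2	candidate	unknown
KLF5	candidate	unknown
PRDM1	candidate	unknown
TMEM59	candidate	unknown
COLCA1	candidate	unknown
LAMA5	candidate	unknown
PREX1	candidate	unknown
TNS3	candidate	unknown
COLCA2	candidate	unknown
LAMC1	candidate	unknown
PTPN1	candidate	unknown
TOX2	candidate	unknown
COX14	candidate	unknown
LGR5	candidate	unknown
PTPN12	candidate	unknown
TP53BP1	candidate	unknown
CRTC3	candidate	unknown
LIG1	candidate	unknown
RBBP8	candidate	unknown
TTC22	candidate	unknown
CTNNB1	candidate	unknown
LIMA1	candidate	unknown
RHPN2	candidate	unknown
VTI1A	candidate	unknown
DCLRE1C	candidate	unknown
LIMK2	candidate	unknown
RPS20	candidate	unknown
WNT4	candidate	unknown
DIP2B	candidate	unknown
LRP1	candidate	unknown
RTEL1	candidate	unknown
XRCC2	candidate	unknown
DUSP10	candidate	unknown
MACC1	candidate	unknown
SATB2-AS1	candidate	unknown
ZAP70	candidate	unknown
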