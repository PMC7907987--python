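gene	category	therapeutic_target
APC	HIGH_PENETRANT	false
BAP1	HIGH_PENETRANT	false
BRCA1	HIGH_PENETRANT	true
BRCA2	HIGH_PENETRANT	true
DICER1	HIGH_PENETRANT	false
FH	HIGH_PENETRANT	false
HOXB13	HIGH_PENETRANT	false
MLH1	HIGH_PENETRANT	true
MSH2	HIGH_PENETRANT	true
PALB2	HIGH_PENETRANT	true
PMS2	HIGH_PENETRANT	true
POT1	HIGH_PENETRANT	false
RB1	HIGH_PENETRANT	false
ATM	MODERATE_PENETRANT	true
BARD1	MODERATE_PENETRANT	false
BRIP1	MODERATE_PENETRANT	true
CHEK2	MODERATE_PENETRANT	false
MITF	MODERATE_PENETRANT	false
MRE11A	MODERATE_PENETRANT	false
MUTYH	MODERATE_PENETRANT	false
NF1	MODERATE_PENETRANT	false
RAD50	MODERATE_PENETRANT	false
RAD51C	MODERATE_PENETRANT	false
SMARCB1	MODERATE_PENETRANT	false
BLM	AR_CANCER_RISK	false
CASP8	AR_CANCER_RISK	false
ERCC1	AR_CANCER_RISK	false
ERCC2	AR_CANCER_RISK	false
ERCC3	AR_CANCER_RISK	false
ERCC4	AR_CANCER_RISK	false
FANCA	AR_CANCER_RISK	false
FANCC	AR_CANCER_RISK	false
FANCG	AR_CANCER_RISK	false
FANCM	AR_CANCER_RISK	false
HAX1	AR_CANCER_RISK	false
MPL	AR_CANCER_RISK	false
NBN	AR_CANCER_RISK	false
SBDS	AR_CANCER_RISK	false
XPC	AR_CANCER_RISK	false
PARK2	AR_NONCANCER	false
WRN	AR_NONCANCER	false
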