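symbol	risk_category	acmg_reportable	inheritance
BRCA1	high	yes	AD
BRCA2	high	yes	AD_AR
PDE11A	novel	no	AD
ATM	moderate	no	AD_AR
ERCC3	not_established	no	AR
FANCI	not_established	no	AR
LIG4	novel	no	AR
MSR1	novel	no	AD
ATR	not_established	no	AD_AR
CHEK2	moderate	no	AD
FANCB	not_established	no	XLR
FANCC	not_established	no	AD_AR
FANCF	not_established	no	AR
FANCL	not_established	no	AR
FANCM	not_established	no	AD_AR
MLH1	not_established	yes	AD_AR
NBN	moderate	no	AD_AR
POLH	not_established	no	AR
PTEN	high	yes	AD
RAD51C	not_established	no	AD_AR
RECQL4	not_established	no	AR
SDHB	not_established	yes	AD
WRN	not_established	no	AR
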