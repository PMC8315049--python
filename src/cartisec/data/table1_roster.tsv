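gene_symbol	group	dex_direction	dex_consistent
ELN	I	increase	NA
IGFBP4	I	increase	NA
IGFBP7	I	increase	NA
LOX	I	increase	NA
SERPINA1	I	increase	increase
SPOCK1	I	increase	increase
SPON1	I	increase	NA
COL9A2	I	decrease	NA
ECRG4	I	decrease	NA
IGF2	I	decrease	NA
AEBP1	I	no_change	NA
CDON	I	no_change	NA
CGREF1	I	no_change	NA
CHRDL2	I	no_change	NA
CLSTN1	I	no_change	NA
CNMD	I	no_change	NA
COL2A1	I	no_change	NA
COL9A3	I	no_change	NA
CTHRC1	I	no_change	NA
EDIL3	I	no_change	NA
EGFR	I	no_change	NA
EIF5B	I	no_change	NA
GOLM1	I	no_change	NA
GREM1	I	no_change	NA
LTBP3	I	no_change	NA
MIA	I	no_change	NA
NUDC	I	no_change	NA
PROS1	I	no_change	NA
PSMA6	I	no_change	NA
SCG5	I	no_change	NA
SULF2	I	no_change	NA
SUSD5	I	no_change	NA
AGT	II	increase	increase
ACTA2	II	no_change	NA
ACTB	II	no_change	NA
ACTN4	II	no_change	NA
ARCN1	II	no_change	NA
ARHGDIA	II	no_change	NA
BLVRB	II	no_change	NA
CALM1	II	no_change	NA
CAPN2	II	no_change	NA
CFL1	II	no_change	NA
CNPY4	II	no_change	NA
COPE	II	no_change	NA
CTSB	II	no_change	NA
DBI	II	no_change	NA
DSTN	II	no_change	NA
EFEMP1	II	no_change	NA
FLNB	II	no_change	NA
FSCN1	II	no_change	NA
GAPDH	II	no_change	NA
GSTM2	II	no_change	NA
GSTP1	II	no_change	NA
HBA1	II	no_change	NA
HNRNPA1	II	no_change	NA
HNRNPA2B1	II	no_change	NA
HNRNPD	II	no_change	NA
HSP90AA1	II	no_change	NA
HSP90AB1	II	no_change	NA
HSP90B1	II	no_change	NA
HSPA8	II	no_change	NA
LASP1	II	no_change	NA
MAP4	II	no_change	NA
NCL	II	no_change	NA
PCBP1	II	no_change	NA
PCMT1	II	no_change	NA
PFN1	II	no_change	NA
PGAM1	II	no_change	NA
PGD	II	no_change	NA
PGK1	II	no_change	NA
PGM1	II	no_change	NA
PHGDH	II	no_change	NA
PKM2	II	no_change	NA
PPIA	II	no_change	NA
PRDX2	II	no_change	NA
PRDX5	II	no_change	NA
PRDX6	II	no_change	NA
PSMB5	II	no_change	NA
PSMB6	II	no_change	NA
RAN	II	no_change	NA
RPL10A	II	no_change	NA
RPL12	II	no_change	NA
RPLP0	II	no_change	NA
RPLP2	II	no_change	NA
RPS21	II	no_change	NA
RPSA	II	no_change	NA
RRBP1	II	no_change	NA
ST13	II	no_change	NA
TARS	II	no_change	NA
TPM3	II	no_change	NA
TPT1	II	no_change	NA
TUBA1D	II	no_change	NA
TXNDC5	II	no_change	NA
G5E6G2	II	no_change	NA
VIM	II	no_change	NA
YBX1	II	no_change	NA
DKK3	III	increase	NA
SAA1	III	increase	NA
TNFRSF6B	III	increase	NA
ANXA8	III	decrease	NA
BMP1	III	decrease	NA
C1S	III	decrease	NA
CATHL1	III	decrease	NA
CCL5	III	decrease	NA
CDA	III	decrease	NA
CHI3L1	III	decrease	NA
CSF1	III	decrease	NA
EEF1G	III	decrease	NA
FBN2	III	decrease	NA
GDF6	III	decrease	NA
HAPLN3	III	decrease	NA
HP	III	decrease	NA
IGFBP5	III	decrease	NA
INHBA	III	decrease	NA
LGALS1	III	decrease	NA
LTBP1	III	decrease	NA
MMP1	III	decrease	NA
MMP13	III	decrease	NA
MMP3	III	decrease	NA
MMP9	III	decrease	NA
OAT	III	decrease	NA
OLFML2B	III	decrease	NA
PLEC	III	decrease	NA
S100A2	III	decrease	NA
SEMA3C	III	decrease	NA
SERPING1	III	decrease	NA
TGFB2	III	decrease	NA
THBS2	III	decrease	NA
VASN	III	decrease	NA
VCAM1	III	decrease	NA
ADAMTSL4	III	no_change	NA
ALYREF	III	no_change	NA
ANXA2	III	no_change	NA
APOD	III	no_change	NA
ATP5A1	III	no_change	NA
C1R	III	no_change	NA
C3	III	no_change	NA
CAPG	III	no_change	NA
CCDC80	III	no_change	NA
CD14	III	no_change	NA
CD44	III	no_change	NA
CFB	III	no_change	NA
CKAP4	III	no_change	NA
COL6A1	III	no_change	NA
COL6A2	III	no_change	NA
COL6A2_2	III	no_change	NA
ECM1	III	no_change	NA
EEF1A1	III	no_change	NA
EEF1D	III	no_change	NA
EFNA1	III	no_change	NA
FN1	III	no_change	NA
H2AFZ	III	no_change	NA
HIST1H1D	III	no_change	NA
HIST1H2AC	III	no_change	NA
HIST1H2AJ	III	no_change	NA
HIST1H4D	III	no_change	NA
HIST2H2BF	III	no_change	NA
HIST2H3PS2	III	no_change	NA
HMGB1	III	no_change	NA
HMGN3	III	no_change	NA
HNRNPA3	III	no_change	NA
HSPE1	III	no_change	NA
IGFBP3	III	no_change	NA
LCN2	III	no_change	NA
LGALS3	III	no_change	NA
LMNA	III	no_change	NA
LMNB1	III	no_change	NA
LMNB2	III	no_change	NA
LTBP2	III	no_change	NA
LUM	III	no_change	NA
M-SAA3.2	III	no_change	NA
MT2	III	no_change	NA
MYL6	III	no_change	NA
OLFML3	III	no_change	NA
ORM1	III	no_change	NA
PRELP	III	no_change	NA
RBMX	III	no_change	NA
S100A4	III	no_change	NA
SAA3	III	no_change	NA
SDC4	III	no_change	NA
SERPINC1	III	no_change	NA
SERPINE1	III	no_change	NA
SERPINH1	III	no_change	NA
SOD2	III	no_change	NA
TMA7	III	no_change	NA
TNC	III	no_change	NA
TNFRSF11B	III	no_change	NA
TTR	III	no_change	NA
CTGF	NA	increase	increase
NUCB1	NA	decrease	decrease
RPL36A	NA	decrease	decrease
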