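symbol	chromosome	region_class
RPS4Y1	Y	MSY
ZFY	Y	MSY
USP9Y	Y	MSY
DDX3Y	Y	MSY
UTY	Y	MSY
TMSB4Y	Y	MSY
NLGN4Y	Y	MSY
KDM5D	Y	MSY
EIF1AY	Y	MSY
RPS4Y2	Y	MSY
PRKY	Y	MSY
TXLNGY	Y	MSY
CD99	X;Y	PAR
SLC25A6	X;Y	PAR
ASMTL	X;Y	PAR
P2RY8	X;Y	PAR
AKAP17A	X;Y	PAR
GTPBP6	X;Y	PAR
ZBED1	X;Y	PAR
DHRSX	X;Y	PAR
CSF2RA	X;Y	PAR
IL3RA	X;Y	PAR
RPS4X	X	X_nonPAR
DDX3X	X	X_nonPAR
KDM6A	X	X_nonPAR
EIF1AX	X	X_nonPAR
XIST	X	X_nonPAR
CD19	16	AUTOSOME
CD14	5	AUTOSOME
CD16	1	AUTOSOME
CD56	11	AUTOSOME
CD8	2	AUTOSOME
CD4	12	AUTOSOME
FCGR3A	1	AUTOSOME
NCAM1	11	AUTOSOME
CD8A	2	AUTOSOME
MT-ND1	MT	AUTOSOME
MT-ND2	MT	AUTOSOME
MT-ND3	MT	AUTOSOME
MT-ND4	MT	AUTOSOME
MT-ND4L	MT	AUTOSOME
MT-ND5	MT	AUTOSOME
MT-ND6	MT	AUTOSOME
MT-CO1	MT	AUTOSOME
MT-CO2	MT	AUTOSOME
MT-CO3	MT	AUTOSOME
MT-ATP6	MT	AUTOSOME
MT-ATP8	MT	AUTOSOME
MT-CYB	MT	AUTOSOME
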