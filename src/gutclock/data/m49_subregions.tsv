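country	subregion
CHN	EA
JPN	EA
KOR	EA
MNG	EA
USA	NA
CAN	NA
SWE	NE
DNK	NE
FIN	NE
NOR	NE
ISL	NE
GBR	NE
IRL	NE
EST	NE
LVA	NE
LTU	NE
ITA	SE
ESP	SE
PRT	SE
GRC	SE
HRV	SE
SVN	SE
MKD	SE
SRB	SE
FRA	WE
DEU	WE
NLD	WE
BEL	WE
AUT	WE
CHE	WE
LUX	WE
HUN	CE
POL	CE
CZE	CE
SVK	CE
RUS	EE
UKR	EE
BLR	EE
MDA	EE
ROU	EE
BGR	EE
IND	SA
BGD	SA
PAK	SA
LKA	SA
IDN	SEA
MYS	SEA
PHL	SEA
SGP	SEA
THA	SEA
VNM	SEA
KHM	SEA
MMR	SEA
LAO	SEA
BRN	SEA
ISR	WA
TUR	WA
SAU	WA
ARE	WA
JOR	WA
KAZ	CA
KGZ	CA
TJK	CA
TZA	SSA
GHA	SSA
NGA	SSA
ETH	SSA
MDG	SSA
CMR	SSA
LBR	SSA
EGY	NAF
MAR	NAF
TUN	NAF
BRA	SAM
PER	SAM
ARG	SAM
COL	SAM
SLV	CAM
MEX	CAM
GTM	CAM
AUS	ANZ
NZL	ANZ
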