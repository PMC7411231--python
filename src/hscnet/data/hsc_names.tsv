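External_quiescence	External quiescence
External_cycling	External cycling
PI3K	PI3K
TSC1_2	TSC1/2
mTORC1	mTORC1
FOXO3A	FOXO3A
ATM	ATM
Mitochondria	Mitochondria
ROS	ROS
Autophagy	Autophagy
RAS	RAS
ETS	ETS
MEF	MEF
GSK3B	GSK3β
CTNNB1	CTNNB1
cMYC	cMYC
BMI1	BMI1
MDM2	MDM2
TP53	TP53
CDKN1C	CDKN1C
CDKN1A	CDKN1A
CDKN1B	CDKN1B
GFI1	GFI1
RB	RB
E2F	E2F
CCND1	CCND1
CCNE1	CCNE1
S_phase	S-phase
AKT	AKT
CDKN2A	CDKN2A
CDKN2D	CDKN2D
Pro_apoptotic	Pro-apoptotic proteins
Anti_apoptotic	Anti-apoptotic proteins
CYCS	CYCS
Apoptosis	Apoptosis
Senescence	Senescence
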