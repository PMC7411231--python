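# Boolean network model of hematopoietic stem cell quiescence and awakening.
# Two input nodes (External_quiescence, External_cycling) encode niche stimuli;
# node names are ASCII-normalized (see hsc_names.tsv for display names).
targets, factors
External_quiescence, External_quiescence
External_cycling, External_cycling
PI3K, RAS
TSC1_2, !AKT
mTORC1, !TSC1_2
FOXO3A, External_quiescence & !AKT
ATM, FOXO3A
Mitochondria, mTORC1
ROS, Mitochondria | !ATM | !FOXO3A | !BMI1 | !TP53
Autophagy, FOXO3A & ROS & !mTORC1
RAS, External_cycling
ETS, RAS & !MEF
MEF, RAS
GSK3B, !AKT
CTNNB1, !GSK3B
cMYC, CTNNB1 & !GSK3B
BMI1, cMYC | (FOXO3A & ATM)
MDM2, (TP53 | MEF) & !CDKN2D & !ATM
TP53, !MDM2
CDKN1C, External_quiescence | FOXO3A
CDKN1A, (TP53 | FOXO3A | External_quiescence | GFI1) & !cMYC
CDKN1B, FOXO3A
GFI1, TP53
RB, !CCND1 & !CCNE1
E2F, !RB & !GFI1
CCND1, !CDKN2A & !CDKN1C & cMYC
CCNE1, !CDKN1C & ((!CDKN1A & !CDKN1B) | CCND1) & E2F
S_phase, E2F & CCNE1
AKT, PI3K
CDKN2A, (ETS | ROS) & !BMI1
CDKN2D, (E2F | ROS) & !BMI1
Pro_apoptotic, ROS & TP53 & !AKT
Anti_apoptotic, (RAS | External_quiescence) & !GSK3B
CYCS, Pro_apoptotic & !Anti_apoptotic
Apoptosis, CYCS & !AKT
Senescence, (CDKN2A & ROS) | (TP53 & ROS & CDKN1A)
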