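channel	lobe
Fp1	frontal
Fpz	frontal
Fp2	frontal
AF7	frontal
AF3	frontal
AF4	frontal
AF8	frontal
F7	frontal
F5	frontal
F3	frontal
F1	frontal
Fz	frontal
F2	frontal
F4	frontal
F6	frontal
F8	frontal
FC5	frontal
FC3	frontal
FC1	frontal
FCz	frontal
FC2	frontal
FC4	frontal
FC6	frontal
FT7	temporal_left
T7	temporal_left
TP7	temporal_left
M1	temporal_left
FT8	temporal_right
T8	temporal_right
TP8	temporal_right
M2	temporal_right
C5	parietal
C3	parietal
C1	parietal
Cz	parietal
C2	parietal
C4	parietal
C6	parietal
CP5	parietal
CP3	parietal
CP1	parietal
CPz	parietal
CP2	parietal
CP4	parietal
CP6	parietal
P7	parietal
P5	parietal
P3	parietal
P1	parietal
Pz	parietal
P2	parietal
P4	parietal
P6	parietal
P8	parietal
PO7	occipital
PO5	occipital
PO3	occipital
POz	occipital
PO4	occipital
PO6	occipital
PO8	occipital
O1	occipital
Oz	occipital
O2	occipital
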