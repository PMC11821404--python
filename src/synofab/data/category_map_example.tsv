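# Example gene -> category map covering the marker proteins of each class.
# Admissible labels: plasma, cartilage, neutrophil, erythrocyte, platelet,
# generic_cell, noncategorized. Genes absent from the map default to
# noncategorized.
ALB	plasma
HP	plasma
HRG	plasma
CP	plasma
CRP	plasma
CPN1	plasma
TF	plasma
A2M	plasma
COMP	cartilage
CRTAC1	cartilage
PRG4	cartilage
PCOLCE	cartilage
FN1	cartilage
ACAN	cartilage
ELANE	neutrophil
MPO	neutrophil
ENO1	neutrophil
CTSG	neutrophil
DEFA1	neutrophil
PRTN3	neutrophil
S100A8	neutrophil
S100A9	neutrophil
HBB	erythrocyte
HBA1	erythrocyte
CA1	erythrocyte
PPBP	platelet
PF4	platelet
THBS1	platelet
H2AC21	generic_cell
H4C1	generic_cell
ACTC1	generic_cell
ARPC2	generic_cell
ACTR3	generic_cell
GAPDH	generic_cell
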