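# Molecular-weight annotations for the size-stratified plasma-vs-SF analysis.
# assembly_kda is the mass of the circulating assembly (multimer/complex) where
# the protein does not circulate as a monomer; values rounded from UniProt and
# standard plasma-protein literature. Editable: rows may be added or changed.
gene	monomer_kda	assembly_kda
ALB	66.5
TF	76.8
HPX	57.0
SERPINA1	46.7
GC	52.9
AGT	53.0
AHSG	49.0
CFB	86.0
CP	132.0
CFH	155.0
C3	187.0
C4A	193.0
IGHG1	51.0	150.0
IGHA1	53.0	160.0
FGA	95.0	340.0
FN1	220.0	440.0
APOB	515.0	550.0
A2M	163.0	720.0
IGHM	65.0	970.0
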