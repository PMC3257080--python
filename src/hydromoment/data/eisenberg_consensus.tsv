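# Eisenberg consensus hydrophobicity scale (dimensionless, one value per
# residue type).
# Columns: resname<TAB>h
ALA	0.25
ARG	-1.80
ASN	-0.64
ASP	-0.72
CYS	0.04
GLN	-0.69
GLU	-0.62
GLY	0.16
HIS	-0.40
ILE	0.73
LEU	0.53
LYS	-1.10
MET	0.26
PHE	0.61
PRO	-0.07
SER	-0.26
THR	-0.18
TRP	0.37
TYR	0.02
VAL	0.54
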