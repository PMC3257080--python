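# Published reference solvent-accessible surface areas (A^2) of residue
# type X in an extended (phi = psi = 180 deg) Gly-X-Gly tripeptide,
# computed with the ASC program at a 1.4 A probe radius. Selectable as an
# alternative to the reference table the package computes itself
# (reference_mode = "published" vs "computed").
# Columns: resname<TAB>asa_A2
ALA	116.5
ARG	249.7
ASN	163.2
ASP	156.2
CYS	140.2
GLN	188.9
GLU	183.8
GLY	84.9
HIS	204.3
ILE	183.6
LEU	193.5
LYS	211.3
MET	205.9
PHE	223.7
PRO	148.3
SER	124.8
THR	144.1
TRP	266.3
TYR	236.0
VAL	158.0
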