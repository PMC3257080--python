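# United-atom (heavy-atom) van der Waals radii for protein atoms, Chothia/NACCESS-style.
# Columns: resname<TAB>atom<TAB>radius_angstrom
ALA	N	1.65
ALA	CA	1.87
ALA	C	1.76
ALA	O	1.40
ALA	CB	1.87
ALA	OXT	1.40
ARG	N	1.65
ARG	CA	1.87
ARG	C	1.76
ARG	O	1.40
ARG	CB	1.87
ARG	CG	1.87
ARG	CD	1.87
ARG	NE	1.65
ARG	CZ	1.76
ARG	NH1	1.65
ARG	NH2	1.65
ARG	OXT	1.40
ASN	N	1.65
ASN	CA	1.87
ASN	C	1.76
ASN	O	1.40
ASN	CB	1.87
ASN	CG	1.76
ASN	OD1	1.40
ASN	ND2	1.65
ASN	OXT	1.40
ASP	N	1.65
ASP	CA	1.87
ASP	C	1.76
ASP	O	1.40
ASP	CB	1.87
ASP	CG	1.76
ASP	OD1	1.40
ASP	OD2	1.40
ASP	OXT	1.40
CYS	N	1.65
CYS	CA	1.87
CYS	C	1.76
CYS	O	1.40
CYS	CB	1.87
CYS	SG	1.85
CYS	OXT	1.40
GLN	N	1.65
GLN	CA	1.87
GLN	C	1.76
GLN	O	1.40
GLN	CB	1.87
GLN	CG	1.87
GLN	CD	1.76
GLN	OE1	1.40
GLN	NE2	1.65
GLN	OXT	1.40
GLU	N	1.65
GLU	CA	1.87
GLU	C	1.76
GLU	O	1.40
GLU	CB	1.87
GLU	CG	1.87
GLU	CD	1.76
GLU	OE1	1.40
GLU	OE2	1.40
GLU	OXT	1.40
GLY	N	1.65
GLY	CA	1.87
GLY	C	1.76
GLY	O	1.40
GLY	OXT	1.40
HIS	N	1.65
HIS	CA	1.87
HIS	C	1.76
HIS	O	1.40
HIS	CB	1.87
HIS	CG	1.76
HIS	ND1	1.65
HIS	CD2	1.76
HIS	CE1	1.76
HIS	NE2	1.65
HIS	OXT	1.40
ILE	N	1.65
ILE	CA	1.87
ILE	C	1.76
ILE	O	1.40
ILE	CB	1.87
ILE	CG1	1.87
ILE	CG2	1.87
ILE	CD1	1.87
ILE	OXT	1.40
LEU	N	1.65
LEU	CA	1.87
LEU	C	1.76
LEU	O	1.40
LEU	CB	1.87
LEU	CG	1.87
LEU	CD1	1.87
LEU	CD2	1.87
LEU	OXT	1.40
LYS	N	1.65
LYS	CA	1.87
LYS	C	1.76
LYS	O	1.40
LYS	CB	1.87
LYS	CG	1.87
LYS	CD	1.87
LYS	CE	1.87
LYS	NZ	1.65
LYS	OXT	1.40
MET	N	1.65
MET	CA	1.87
MET	C	1.76
MET	O	1.40
MET	CB	1.87
MET	CG	1.87
MET	SD	1.85
MET	CE	1.87
MET	OXT	1.40
PHE	N	1.65
PHE	CA	1.87
PHE	C	1.76
PHE	O	1.40
PHE	CB	1.87
PHE	CG	1.76
PHE	CD1	1.76
PHE	CD2	1.76
PHE	CE1	1.76
PHE	CE2	1.76
PHE	CZ	1.76
PHE	OXT	1.40
PRO	N	1.65
PRO	CA	1.87
PRO	C	1.76
PRO	O	1.40
PRO	CB	1.87
PRO	CG	1.87
PRO	CD	1.87
PRO	OXT	1.40
SER	N	1.65
SER	CA	1.87
SER	C	1.76
SER	O	1.40
SER	CB	1.87
SER	OG	1.40
SER	OXT	1.40
THR	N	1.65
THR	CA	1.87
THR	C	1.76
THR	O	1.40
THR	CB	1.87
THR	OG1	1.40
THR	CG2	1.87
THR	OXT	1.40
TRP	N	1.65
TRP	CA	1.87
TRP	C	1.76
TRP	O	1.40
TRP	CB	1.87
TRP	CG	1.76
TRP	CD1	1.76
TRP	CD2	1.76
TRP	NE1	1.65
TRP	CE2	1.76
TRP	CE3	1.76
TRP	CZ2	1.76
TRP	CZ3	1.76
TRP	CH2	1.76
TRP	OXT	1.40
TYR	N	1.65
TYR	CA	1.87
TYR	C	1.76
TYR	O	1.40
TYR	CB	1.87
TYR	CG	1.76
TYR	CD1	1.76
TYR	CD2	1.76
TYR	CE1	1.76
TYR	CE2	1.76
TYR	CZ	1.76
TYR	OH	1.40
TYR	OXT	1.40
VAL	N	1.65
VAL	CA	1.87
VAL	C	1.76
VAL	O	1.40
VAL	CB	1.87
VAL	CG1	1.87
VAL	CG2	1.87
VAL	OXT	1.40
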