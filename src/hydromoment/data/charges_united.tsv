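# United/extended-atom partial charges (CHARMM19-style protein topology, internal-residue values; no terminal patches). Hydrogen charges are folded into the bonded heavy atom by construction of the united-atom model.
# Columns: resname<TAB>atom<TAB>charge_e
ALA	N	-0.35
ALA	CA	0.10
ALA	C	0.55
ALA	O	-0.55
ALA	CB	0.00
ALA	OXT	-0.55
ARG	N	-0.35
ARG	CA	0.10
ARG	C	0.55
ARG	O	-0.55
ARG	CB	0.00
ARG	CG	0.00
ARG	CD	0.10
ARG	NE	-0.40
ARG	CZ	0.50
ARG	NH1	-0.45
ARG	NH2	-0.45
ARG	OXT	-0.55
ASN	N	-0.35
ASN	CA	0.10
ASN	C	0.55
ASN	O	-0.55
ASN	CB	0.00
ASN	CG	0.55
ASN	OD1	-0.55
ASN	ND2	-0.60
ASN	OXT	-0.55
ASP	N	-0.35
ASP	CA	0.10
ASP	C	0.55
ASP	O	-0.55
ASP	CB	-0.16
ASP	CG	0.36
ASP	OD1	-0.60
ASP	OD2	-0.60
ASP	OXT	-0.55
CYS	N	-0.35
CYS	CA	0.10
CYS	C	0.55
CYS	O	-0.55
CYS	CB	0.19
CYS	SG	-0.19
CYS	OXT	-0.55
GLN	N	-0.35
GLN	CA	0.10
GLN	C	0.55
GLN	O	-0.55
GLN	CB	0.00
GLN	CG	0.00
GLN	CD	0.55
GLN	OE1	-0.55
GLN	NE2	-0.60
GLN	OXT	-0.55
GLU	N	-0.35
GLU	CA	0.10
GLU	C	0.55
GLU	O	-0.55
GLU	CB	0.00
GLU	CG	-0.16
GLU	CD	0.36
GLU	OE1	-0.60
GLU	OE2	-0.60
GLU	OXT	-0.55
GLY	N	-0.35
GLY	CA	0.10
GLY	C	0.55
GLY	O	-0.55
GLY	OXT	-0.55
HIS	N	-0.35
HIS	CA	0.10
HIS	C	0.55
HIS	O	-0.55
HIS	CB	0.00
HIS	CG	0.10
HIS	ND1	-0.40
HIS	CD2	0.10
HIS	CE1	0.30
HIS	NE2	-0.40
HIS	OXT	-0.55
ILE	N	-0.35
ILE	CA	0.10
ILE	C	0.55
ILE	O	-0.55
ILE	CB	0.00
ILE	CG1	0.00
ILE	CG2	0.00
ILE	CD1	0.00
ILE	OXT	-0.55
LEU	N	-0.35
LEU	CA	0.10
LEU	C	0.55
LEU	O	-0.55
LEU	CB	0.00
LEU	CG	0.00
LEU	CD1	0.00
LEU	CD2	0.00
LEU	OXT	-0.55
LYS	N	-0.35
LYS	CA	0.10
LYS	C	0.55
LYS	O	-0.55
LYS	CB	0.00
LYS	CG	0.00
LYS	CD	0.00
LYS	CE	0.25
LYS	NZ	-0.30
LYS	OXT	-0.55
MET	N	-0.35
MET	CA	0.10
MET	C	0.55
MET	O	-0.55
MET	CB	0.00
MET	CG	0.06
MET	SD	-0.12
MET	CE	0.06
MET	OXT	-0.55
PHE	N	-0.35
PHE	CA	0.10
PHE	C	0.55
PHE	O	-0.55
PHE	CB	0.00
PHE	CG	0.00
PHE	CD1	0.00
PHE	CD2	0.00
PHE	CE1	0.00
PHE	CE2	0.00
PHE	CZ	0.00
PHE	OXT	-0.55
PRO	N	-0.20
PRO	CA	0.10
PRO	C	0.55
PRO	O	-0.55
PRO	CB	0.00
PRO	CG	0.00
PRO	CD	0.10
PRO	OXT	-0.55
SER	N	-0.35
SER	CA	0.10
SER	C	0.55
SER	O	-0.55
SER	CB	0.25
SER	OG	-0.65
SER	OXT	-0.55
THR	N	-0.35
THR	CA	0.10
THR	C	0.55
THR	O	-0.55
THR	CB	0.25
THR	OG1	-0.65
THR	CG2	0.00
THR	OXT	-0.55
TRP	N	-0.35
TRP	CA	0.10
TRP	C	0.55
TRP	O	-0.55
TRP	CB	0.00
TRP	CG	-0.03
TRP	CD1	0.06
TRP	CD2	0.10
TRP	NE1	-0.36
TRP	CE2	-0.04
TRP	CE3	0.00
TRP	CZ2	0.00
TRP	CZ3	0.00
TRP	CH2	0.00
TRP	OXT	-0.55
TYR	N	-0.35
TYR	CA	0.10
TYR	C	0.55
TYR	O	-0.55
TYR	CB	0.00
TYR	CG	0.00
TYR	CD1	0.00
TYR	CD2	0.00
TYR	CE1	0.00
TYR	CE2	0.00
TYR	CZ	0.25
TYR	OH	-0.65
TYR	OXT	-0.55
VAL	N	-0.35
VAL	CA	0.10
VAL	C	0.55
VAL	O	-0.55
VAL	CB	0.00
VAL	CG1	0.00
VAL	CG2	0.00
VAL	OXT	-0.55
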