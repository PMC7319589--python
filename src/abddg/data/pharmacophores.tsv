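# 8-class pharmacophore assignment for heavy atoms of the 20 standard residues
# classes: hydrophobic positive negative acceptor donor aromatic sulfur neutral
residue	atom	classes
ALA	N	donor
ALA	CA	hydrophobic
ALA	C	neutral
ALA	O	acceptor
ALA	CB	hydrophobic
ALA	OXT	negative,acceptor
ARG	N	donor
ARG	CA	hydrophobic
ARG	C	neutral
ARG	O	acceptor
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	hydrophobic
ARG	NE	positive,donor
ARG	CZ	neutral
ARG	NH1	positive,donor
ARG	NH2	positive,donor
ARG	OXT	negative,acceptor
ASN	N	donor
ASN	CA	hydrophobic
ASN	C	neutral
ASN	O	acceptor
ASN	CB	hydrophobic
ASN	CG	neutral
ASN	OD1	acceptor
ASN	ND2	donor
ASN	OXT	negative,acceptor
ASP	N	donor
ASP	CA	hydrophobic
ASP	C	neutral
ASP	O	acceptor
ASP	CB	hydrophobic
ASP	CG	neutral
ASP	OD1	negative,acceptor
ASP	OD2	negative,acceptor
ASP	OXT	negative,acceptor
CYS	N	donor
CYS	CA	hydrophobic
CYS	C	neutral
CYS	O	acceptor
CYS	CB	hydrophobic
CYS	SG	sulfur
CYS	OXT	negative,acceptor
GLN	N	donor
GLN	CA	hydrophobic
GLN	C	neutral
GLN	O	acceptor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	neutral
GLN	OE1	acceptor
GLN	NE2	donor
GLN	OXT	negative,acceptor
GLU	N	donor
GLU	CA	hydrophobic
GLU	C	neutral
GLU	O	acceptor
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	neutral
GLU	OE1	negative,acceptor
GLU	OE2	negative,acceptor
GLU	OXT	negative,acceptor
GLY	N	donor
GLY	CA	hydrophobic
GLY	C	neutral
GLY	O	acceptor
GLY	OXT	negative,acceptor
HIS	N	donor
HIS	CA	hydrophobic
HIS	C	neutral
HIS	O	acceptor
HIS	CB	hydrophobic
HIS	CG	aromatic
HIS	ND1	aromatic,positive,donor,acceptor
HIS	CD2	aromatic
HIS	CE1	aromatic
HIS	NE2	aromatic,positive,donor,acceptor
HIS	OXT	negative,acceptor
ILE	N	donor
ILE	CA	hydrophobic
ILE	C	neutral
ILE	O	acceptor
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
ILE	OXT	negative,acceptor
LEU	N	donor
LEU	CA	hydrophobic
LEU	C	neutral
LEU	O	acceptor
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LEU	OXT	negative,acceptor
LYS	N	donor
LYS	CA	hydrophobic
LYS	C	neutral
LYS	O	acceptor
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	hydrophobic
LYS	NZ	positive,donor
LYS	OXT	negative,acceptor
MET	N	donor
MET	CA	hydrophobic
MET	C	neutral
MET	O	acceptor
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	sulfur
MET	CE	hydrophobic
MET	OXT	negative,acceptor
PHE	N	donor
PHE	CA	hydrophobic
PHE	C	neutral
PHE	O	acceptor
PHE	CB	hydrophobic
PHE	CG	aromatic,hydrophobic
PHE	CD1	aromatic,hydrophobic
PHE	CD2	aromatic,hydrophobic
PHE	CE1	aromatic,hydrophobic
PHE	CE2	aromatic,hydrophobic
PHE	CZ	aromatic,hydrophobic
PHE	OXT	negative,acceptor
PRO	N	neutral
PRO	CA	hydrophobic
PRO	C	neutral
PRO	O	acceptor
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	hydrophobic
PRO	OXT	negative,acceptor
SER	N	donor
SER	CA	hydrophobic
SER	C	neutral
SER	O	acceptor
SER	CB	hydrophobic
SER	OG	donor,acceptor
SER	OXT	negative,acceptor
THR	N	donor
THR	CA	hydrophobic
THR	C	neutral
THR	O	acceptor
THR	CB	hydrophobic
THR	OG1	donor,acceptor
THR	CG2	hydrophobic
THR	OXT	negative,acceptor
TRP	N	donor
TRP	CA	hydrophobic
TRP	C	neutral
TRP	O	acceptor
TRP	CB	hydrophobic
TRP	CG	aromatic,hydrophobic
TRP	CD1	aromatic
TRP	CD2	aromatic,hydrophobic
TRP	NE1	aromatic,donor
TRP	CE2	aromatic,hydrophobic
TRP	CE3	aromatic,hydrophobic
TRP	CZ2	aromatic,hydrophobic
TRP	CZ3	aromatic,hydrophobic
TRP	CH2	aromatic,hydrophobic
TRP	OXT	negative,acceptor
TYR	N	donor
TYR	CA	hydrophobic
TYR	C	neutral
TYR	O	acceptor
TYR	CB	hydrophobic
TYR	CG	aromatic,hydrophobic
TYR	CD1	aromatic,hydrophobic
TYR	CD2	aromatic,hydrophobic
TYR	CE1	aromatic,hydrophobic
TYR	CE2	aromatic,hydrophobic
TYR	CZ	aromatic,hydrophobic
TYR	OH	donor,acceptor
TYR	OXT	negative,acceptor
VAL	N	donor
VAL	CA	hydrophobic
VAL	C	neutral
VAL	O	acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
VAL	OXT	negative,acceptor
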