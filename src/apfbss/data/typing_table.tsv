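# Atom typing table: pharmacophoric property vectors per (residue, atom name).
# Columns: residue <TAB> atom <TAB> donor acceptor lipophilicity size electronegativity charge sp2
# Lookup order: exact (residue, atom) -> wildcard ('*', atom, backbone names) ->
#   element fallback ('@element', symbol) -> '@default'.
# Conventions: donors/acceptors encoded on heavy atoms (hydrogens are dropped on
# parsing); size ~ vdW radius relative to carbon; electronegativity ~ Pauling
# scale minus carbon's 2.55; formal charge spread over the equivalent atoms of
# the charged group; sp2 marks aromatic/planar character.
# --- backbone (any residue) ---
*	N	1.0	0.0	0.0	0.90	0.49	0.0	0.0
*	CA	0.0	0.0	0.5	1.00	0.00	0.0	0.0
*	C	0.0	0.0	0.0	1.00	0.00	0.0	0.5
*	O	0.0	1.0	0.0	0.85	0.89	0.0	0.5
*	OXT	0.0	1.0	0.0	0.85	0.89	-0.5	0.5
# --- charged side chains ---
ARG	NE	1.0	0.0	0.0	0.90	0.49	0.33	0.5
ARG	NH1	1.0	0.0	0.0	0.90	0.49	0.33	0.5
ARG	NH2	1.0	0.0	0.0	0.90	0.49	0.33	0.5
ARG	CZ	0.0	0.0	0.0	1.00	0.00	0.0	1.0
LYS	NZ	1.0	0.0	0.0	0.90	0.49	1.0	0.0
ASP	OD1	0.0	1.0	0.0	0.85	0.89	-0.5	0.5
ASP	OD2	0.0	1.0	0.0	0.85	0.89	-0.5	0.5
ASP	CG	0.0	0.0	0.0	1.00	0.00	0.0	0.5
GLU	OE1	0.0	1.0	0.0	0.85	0.89	-0.5	0.5
GLU	OE2	0.0	1.0	0.0	0.85	0.89	-0.5	0.5
GLU	CD	0.0	0.0	0.0	1.00	0.00	0.0	0.5
# --- amides ---
ASN	OD1	0.0	1.0	0.0	0.85	0.89	0.0	0.5
ASN	ND2	1.0	0.0	0.0	0.90	0.49	0.0	0.5
ASN	CG	0.0	0.0	0.0	1.00	0.00	0.0	0.5
GLN	OE1	0.0	1.0	0.0	0.85	0.89	0.0	0.5
GLN	NE2	1.0	0.0	0.0	0.90	0.49	0.0	0.5
GLN	CD	0.0	0.0	0.0	1.00	0.00	0.0	0.5
# --- hydroxyls ---
SER	OG	1.0	0.5	0.0	0.85	0.89	0.0	0.0
THR	OG1	1.0	0.5	0.0	0.85	0.89	0.0	0.0
TYR	OH	1.0	0.3	0.0	0.85	0.89	0.0	0.0
# --- aromatic rings ---
PHE	CG	0.0	0.0	0.8	1.00	0.00	0.0	1.0
PHE	CD1	0.0	0.0	0.8	1.00	0.00	0.0	1.0
PHE	CD2	0.0	0.0	0.8	1.00	0.00	0.0	1.0
PHE	CE1	0.0	0.0	0.8	1.00	0.00	0.0	1.0
PHE	CE2	0.0	0.0	0.8	1.00	0.00	0.0	1.0
PHE	CZ	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TYR	CG	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TYR	CD1	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TYR	CD2	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TYR	CE1	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TYR	CE2	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TYR	CZ	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TRP	NE1	1.0	0.0	0.0	0.90	0.49	0.0	1.0
TRP	CG	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TRP	CD1	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TRP	CD2	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TRP	CE2	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TRP	CE3	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TRP	CZ2	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TRP	CZ3	0.0	0.0	0.8	1.00	0.00	0.0	1.0
TRP	CH2	0.0	0.0	0.8	1.00	0.00	0.0	1.0
HIS	ND1	0.5	0.5	0.0	0.90	0.49	0.0	1.0
HIS	NE2	0.5	0.5	0.0	0.90	0.49	0.0	1.0
HIS	CG	0.0	0.0	0.3	1.00	0.00	0.0	1.0
HIS	CD2	0.0	0.0	0.3	1.00	0.00	0.0	1.0
HIS	CE1	0.0	0.0	0.3	1.00	0.00	0.0	1.0
# --- sulfur ---
CYS	SG	0.3	0.0	0.6	1.10	0.03	0.0	0.0
MET	SD	0.0	0.3	0.6	1.10	0.03	0.0	0.0
# --- element fallbacks (sidechain aliphatic carbons, HET groups, unknowns) ---
@element	C	0.0	0.0	1.0	1.00	0.00	0.0	0.0
@element	N	0.5	0.5	0.0	0.90	0.49	0.0	0.0
@element	O	0.0	1.0	0.0	0.85	0.89	0.0	0.0
@element	S	0.0	0.0	0.6	1.10	0.03	0.0	0.0
@element	P	0.0	0.0	0.0	1.10	-0.36	0.0	0.0
@element	F	0.0	0.3	0.2	0.85	1.43	0.0	0.0
@element	CL	0.0	0.0	0.5	1.05	0.61	0.0	0.0
@element	BR	0.0	0.0	0.6	1.10	0.41	0.0	0.0
@element	I	0.0	0.0	0.7	1.15	0.11	0.0	0.0
@default	-	0.0	0.0	0.0	1.00	0.00	0.0	0.0
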