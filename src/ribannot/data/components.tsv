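# Chemical-component dictionary subset: kind assignment for common comp_ids.
# base = parent nucleobase letter for nucleotides ('-' otherwise).
# comp_ids absent here are classified by atom content (see refdata.residue_kind).
ccd_id	kind	base
A	ribonucleotide	A
C	ribonucleotide	C
G	ribonucleotide	G
U	ribonucleotide	U
I	ribonucleotide	G
N	ribonucleotide	-
PSU	ribonucleotide	U
1MA	ribonucleotide	A
2MG	ribonucleotide	G
7MG	ribonucleotide	G
M2G	ribonucleotide	G
OMC	ribonucleotide	C
OMG	ribonucleotide	G
OMU	ribonucleotide	U
5MC	ribonucleotide	C
5MU	ribonucleotide	U
4SU	ribonucleotide	U
H2U	ribonucleotide	U
UR3	ribonucleotide	U
A2M	ribonucleotide	A
6MZ	ribonucleotide	A
MIA	ribonucleotide	A
YG	ribonucleotide	G
G7M	ribonucleotide	G
DA	deoxyribonucleotide	A
DC	deoxyribonucleotide	C
DG	deoxyribonucleotide	G
DT	deoxyribonucleotide	T
DU	deoxyribonucleotide	U
DI	deoxyribonucleotide	G
DN	deoxyribonucleotide	-
ALA	amino_acid	-
ARG	amino_acid	-
ASN	amino_acid	-
ASP	amino_acid	-
CYS	amino_acid	-
GLN	amino_acid	-
GLU	amino_acid	-
GLY	amino_acid	-
HIS	amino_acid	-
ILE	amino_acid	-
LEU	amino_acid	-
LYS	amino_acid	-
MET	amino_acid	-
PHE	amino_acid	-
PRO	amino_acid	-
SER	amino_acid	-
THR	amino_acid	-
TRP	amino_acid	-
TYR	amino_acid	-
VAL	amino_acid	-
MSE	amino_acid	-
SEC	amino_acid	-
PYL	amino_acid	-
UNK	amino_acid	-
HOH	water	-
DOD	water	-
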