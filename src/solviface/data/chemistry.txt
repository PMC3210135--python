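# Default atom-role dictionary.
#
# Plain lines:  RES  ATOM  flag[,flag...]
#   flags: donor acceptor positive negative hydrophobic
# Directives:
#   @water NAME...          residue names treated as water
#   @base  RES atom,...     base-moiety atom names of a standard nucleotide
#
# Heavy-atom roles only; carbon atoms of known residues default to
# hydrophobic unless listed here.  Histidine ND1/NE2 are donor+acceptor
# and uncharged; terminal amine N is donor only (protonation unknowable
# from coordinates); OXT is an acceptor on every amino acid.

# --- amino-acid backbone ---
ALA N donor
ALA O acceptor
ALA OXT acceptor
ARG N donor
ARG O acceptor
ARG OXT acceptor
ASN N donor
ASN O acceptor
ASN OXT acceptor
ASP N donor
ASP O acceptor
ASP OXT acceptor
CYS N donor
CYS O acceptor
CYS OXT acceptor
GLN N donor
GLN O acceptor
GLN OXT acceptor
GLU N donor
GLU O acceptor
GLU OXT acceptor
GLY N donor
GLY O acceptor
GLY OXT acceptor
HIS N donor
HIS O acceptor
HIS OXT acceptor
ILE N donor
ILE O acceptor
ILE OXT acceptor
LEU N donor
LEU O acceptor
LEU OXT acceptor
LYS N donor
LYS O acceptor
LYS OXT acceptor
MET N donor
MET O acceptor
MET OXT acceptor
PHE N donor
PHE O acceptor
PHE OXT acceptor
PRO O acceptor
PRO OXT acceptor
SER N donor
SER O acceptor
SER OXT acceptor
THR N donor
THR O acceptor
THR OXT acceptor
TRP N donor
TRP O acceptor
TRP OXT acceptor
TYR N donor
TYR O acceptor
TYR OXT acceptor
VAL N donor
VAL O acceptor
VAL OXT acceptor
MSE N donor
MSE O acceptor
MSE OXT acceptor

# --- amino-acid side chains ---
ARG NE donor,positive
ARG NH1 donor,positive
ARG NH2 donor,positive
ASN OD1 acceptor
ASN ND2 donor
ASP OD1 acceptor,negative
ASP OD2 acceptor,negative
CYS SG donor
GLN OE1 acceptor
GLN NE2 donor
GLU OE1 acceptor,negative
GLU OE2 acceptor,negative
HIS ND1 donor,acceptor
HIS NE2 donor,acceptor
LYS NZ donor,positive
MET SD hydrophobic
MSE SE hydrophobic
SER OG donor,acceptor
THR OG1 donor,acceptor
TRP NE1 donor
TYR OH donor,acceptor

# --- water ---
@water HOH WAT DOD
HOH O donor,acceptor
WAT O donor,acceptor
DOD O donor,acceptor

# --- nucleotides: sugar-phosphate polar atoms ---
A P negative
A OP1 acceptor,negative
A OP2 acceptor,negative
A O5' acceptor
A O3' acceptor
A O4' acceptor
A O2' donor,acceptor
G P negative
G OP1 acceptor,negative
G OP2 acceptor,negative
G O5' acceptor
G O3' acceptor
G O4' acceptor
G O2' donor,acceptor
C P negative
C OP1 acceptor,negative
C OP2 acceptor,negative
C O5' acceptor
C O3' acceptor
C O4' acceptor
C O2' donor,acceptor
U P negative
U OP1 acceptor,negative
U OP2 acceptor,negative
U O5' acceptor
U O3' acceptor
U O4' acceptor
U O2' donor,acceptor
DA P negative
DA OP1 acceptor,negative
DA OP2 acceptor,negative
DA O5' acceptor
DA O3' acceptor
DA O4' acceptor
DG P negative
DG OP1 acceptor,negative
DG OP2 acceptor,negative
DG O5' acceptor
DG O3' acceptor
DG O4' acceptor
DC P negative
DC OP1 acceptor,negative
DC OP2 acceptor,negative
DC O5' acceptor
DC O3' acceptor
DC O4' acceptor
DT P negative
DT OP1 acceptor,negative
DT OP2 acceptor,negative
DT O5' acceptor
DT O3' acceptor
DT O4' acceptor
DU P negative
DU OP1 acceptor,negative
DU OP2 acceptor,negative
DU O5' acceptor
DU O3' acceptor
DU O4' acceptor

# --- nucleotides: base polar atoms ---
A N1 acceptor
A N3 acceptor
A N6 donor
A N7 acceptor
DA N1 acceptor
DA N3 acceptor
DA N6 donor
DA N7 acceptor
G N1 donor
G N2 donor
G N3 acceptor
G N7 acceptor
G O6 acceptor
DG N1 donor
DG N2 donor
DG N3 acceptor
DG N7 acceptor
DG O6 acceptor
C O2 acceptor
C N3 acceptor
C N4 donor
DC O2 acceptor
DC N3 acceptor
DC N4 donor
U O2 acceptor
U N3 donor
U O4 acceptor
DU O2 acceptor
DU N3 donor
DU O4 acceptor
T O2 acceptor
T N3 donor
T O4 acceptor
DT O2 acceptor
DT N3 donor
DT O4 acceptor

# --- base-moiety atom sets (duplex merging) ---
@base A N9,C8,N7,C5,C6,N6,N1,C2,N3,C4
@base DA N9,C8,N7,C5,C6,N6,N1,C2,N3,C4
@base G N9,C8,N7,C5,C6,O6,N1,C2,N2,N3,C4
@base DG N9,C8,N7,C5,C6,O6,N1,C2,N2,N3,C4
@base C N1,C2,O2,N3,C4,N4,C5,C6
@base DC N1,C2,O2,N3,C4,N4,C5,C6
@base U N1,C2,O2,N3,C4,O4,C5,C6
@base DU N1,C2,O2,N3,C4,O4,C5,C6
@base T N1,C2,O2,N3,C4,O4,C5,C7,C6
@base DT N1,C2,O2,N3,C4,O4,C5,C7,C6
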