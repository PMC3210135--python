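# Curated monosaccharide residue codes (3-letter HETATM codes).
# One code per line; lines starting with '#' are comments.
# Editable: append codes to recognize additional sugar units.
NAG
NDG
NGA
A2G
GLC
BGC
MAN
BMA
GAL
GLA
FUC
FUL
XYS
XYP
ARA
ARB
RIB
FRU
SIA
SLB
GCU
BDP
IDS
IDR
GCS
KDN
RAM
RHA
ADA
MAL
LAT
SUC
TRE
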