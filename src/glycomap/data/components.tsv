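# comp_name <TAB> category
# Built-in residue component table. Users may extend/override via a file in
# the same format (load_component_table(extra=...)).
ALA	protein
ARG	protein
ASN	protein
ASP	protein
CYS	protein
GLN	protein
GLU	protein
GLY	protein
HIS	protein
ILE	protein
LEU	protein
LYS	protein
MET	protein
PHE	protein
PRO	protein
SER	protein
THR	protein
TRP	protein
TYR	protein
VAL	protein
HOH	water
WAT	water
DOD	water
# pyranoses and amino sugars
MAN	saccharide
BMA	saccharide
GLC	saccharide
BGC	saccharide
GCS	saccharide
PA1	saccharide
GCN	saccharide
NDG	saccharide
NAG	saccharide
GAL	saccharide
GLA	saccharide
XYP	saccharide
FUC	saccharide
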