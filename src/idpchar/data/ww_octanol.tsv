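# Wimley-White whole-residue free energies of transfer from water to n-octanol,
# kcal/mol, water->octanol sign convention (hydrophobic residues negative;
# positive values oppose partitioning into the bilayer interior).
# Residues with ionizable side chains carry a neutral and a charged variant.
# NTERM/CTERM rows are the free terminal-group contributions. The published
# whole-residue scale does not include free termini; the charged-terminal
# constants below were calibrated jointly (their sum is +7.72 kcal/mol) against
# the documented behaviour of the standard partitioning calculator for this
# scale, and split evenly between the two ends. Neutral K/R variants and
# neutral termini are estimates (not part of the published scale) kept only to
# complete the variant set; every charged variant is more hydrophilic (larger
# dG) than its neutral counterpart.
# scale: ww_octanol	units: kcal/mol
code	value	variant
A	0.50	-
R	1.81	charged
R	-0.58	neutral
N	0.85	-
D	3.64	charged
D	0.43	neutral
C	-0.02	-
E	3.63	charged
E	0.11	neutral
Q	0.77	-
G	1.15	-
H	2.33	charged
H	0.11	neutral
I	-1.12	-
L	-1.25	-
K	2.80	charged
K	-0.99	neutral
M	-0.67	-
F	-1.71	-
P	0.14	-
S	0.46	-
T	0.25	-
W	-2.09	-
Y	-0.71	-
V	-0.46	-
NTERM	3.86	charged
NTERM	0.00	neutral
CTERM	3.86	charged
CTERM	0.00	neutral
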