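# Molar extinction coefficients at 214 nm (M^-1 cm^-1) for peptide
# concentration determination by far-UV absorbance: per-side-chain values plus
# one PEPTIDE_BOND contribution per backbone amide (N-1 bonds for N residues).
# P_NTERM replaces the proline value when proline is the first residue (its
# secondary amine is then not part of a peptide bond).
# scale: epsilon214	units: M^-1 cm^-1
code	value	variant
A	0	-
R	102	-
N	136	-
D	0	-
C	225	-
E	0	-
Q	142	-
G	0	-
H	5125	-
I	0	-
L	0	-
K	0	-
M	980	-
F	5200	-
P	2675	-
S	0	-
T	0	-
W	29050	-
Y	5375	-
V	0	-
PEPTIDE_BOND	923	-
P_NTERM	30	-
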