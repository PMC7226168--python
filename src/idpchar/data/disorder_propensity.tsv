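# Per-residue disorder propensity expressed as the fractional difference
# (C_disordered - C_ordered) / C_ordered between amino-acid compositions of
# disordered-protein and folded-structure databases. Positive values mark
# disorder-promoting residues (P, E, S, Q, K, G, D, R), negative values
# order-promoting ones (W, C, F, I, Y, V, L, N, M, T, A, H).
# scale: disorder_propensity	units: dimensionless
code	value	variant
A	-0.077	-
R	0.180	-
N	-0.243	-
D	0.192	-
C	-0.692	-
E	0.736	-
Q	0.318	-
G	0.166	-
H	-0.118	-
I	-0.486	-
L	-0.270	-
K	0.586	-
M	-0.179	-
F	-0.504	-
P	0.987	-
S	0.341	-
T	-0.117	-
W	-0.462	-
Y	-0.434	-
V	-0.301	-
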