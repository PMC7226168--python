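# Bjellqvist pKa set as used by the standard pI calculator: side-chain pKas
# for the seven ionizable residues, terminal-group pKas, residue-specific
# N-terminal amine overrides, and side-chain overrides for D/E when they are
# the C-terminal residue. Variants: sidechain, sidechain_cterm, nterm, default.
# Acid/base assignment (D, E, C, Y, CTERM acidic; H, K, R, NTERM basic) is
# fixed by chemistry and lives in code.
# scale: pka_bjellqvist	units: pH
code	value	variant
D	4.05	sidechain
E	4.45	sidechain
C	9.00	sidechain
Y	10.00	sidechain
H	5.98	sidechain
K	10.00	sidechain
R	12.00	sidechain
D	4.55	sidechain_cterm
E	4.75	sidechain_cterm
NTERM	7.50	default
CTERM	3.55	default
A	7.59	nterm
M	7.00	nterm
S	6.93	nterm
P	8.36	nterm
T	6.82	nterm
V	7.44	nterm
E	7.70	nterm
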