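# Raw per-residue indices for classical (Type-1) pseudo amino acid
# composition: Tanford-derived hydrophobicity, Hopp-Woods hydrophilicity,
# and side-chain mass (Da, rounded as in Chou's classical tables).
# Each column is standardized to zero mean / unit SD over the 20 residues
# at load time.
# columns: residue <TAB> hydrophobicity <TAB> hydrophilicity <TAB> side_chain_mass
A	0.62	-0.5	15
C	0.29	-1.0	47
D	-0.90	3.0	59
E	-0.74	3.0	73
F	1.19	-2.5	91
G	0.48	0.0	1
H	-0.40	-0.5	82
I	1.38	-1.8	57
K	-1.50	3.0	73
L	1.06	-1.8	57
M	0.64	-1.3	75
N	-0.78	0.2	58
P	0.12	0.0	42
Q	-0.85	0.2	72
R	-2.53	3.0	101
S	-0.18	0.3	31
T	-0.05	-0.4	45
V	1.08	-1.5	43
W	0.81	-3.4	130
Y	0.26	-2.3	107
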