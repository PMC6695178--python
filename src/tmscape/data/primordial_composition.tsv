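# Predicted transmembrane amino-acid frequencies (f, residues per helix)
# of primordial membrane proteins, at two points of the evolutionary
# f_Phe coordinate: f_Phe = -2.24 with only the first ten amino acids of
# the genetic code available, and f_Phe = 0 with a sixteen-letter code.
# Rows are ordered by proposed entry of each amino acid into the genetic
# code. Values are one reference outcome of the exponential universal-
# ratio extrapolation; they are shipped so the composition summaries
# (helix length, functional-group sums) can be recomputed from them.
# Columns: one-letter code <TAB> f at f_Phe=-2.24 (k=10) <TAB> f at f_Phe=0 (k=16)
G	2.8	2.7
A	5.5	4.8
D	0.16	0.20
V	4.7	4.0
P	0.94	0.94
S	0.12	0.44
E	0.05	0.13
T	0.75	0.97
L	4.9	4.6
R	1.2	0.85
N	0	0.09
I	0	1.1
Q	0	0.15
H	0	0.02
K	0	0.05
C	0	0.00
F	0	0
Y	0	0
M	0	0
W	0	0
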