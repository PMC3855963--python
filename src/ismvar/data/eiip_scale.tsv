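residue	value
L	0.0000
I	0.0000
N	0.0036
G	0.0050
V	0.0057
E	0.0058
P	0.0198
H	0.0242
K	0.0371
A	0.0373
Y	0.0516
W	0.0548
Q	0.0761
M	0.0823
S	0.0829
C	0.0829
T	0.0941
F	0.0954
R	0.0956
D	0.1263
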