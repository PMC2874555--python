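# BLAS910101	Scaled side chain hydrophobicity values (Black-Mould, 1991)
A	0.616
C	0.68
D	0.028
E	0.043
F	1
G	0.501
H	0.165
I	0.943
K	0.283
L	0.943
M	0.738
N	0.236
P	0.711
Q	0.251
R	0
S	0.359
T	0.45
V	0.825
W	0.878
Y	0.88
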