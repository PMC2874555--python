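# OOBM850105	Optimized side chain interaction parameter (Oobatake et al., 1985)
A	4.55
C	-0.78
D	2.85
E	5.16
F	4.37
G	9.14
H	4.48
I	2.1
K	10.68
L	3.24
M	2.18
N	5.56
P	5.14
Q	4.15
R	5.97
S	6.78
T	8.6
V	3.81
W	1.97
Y	2.4
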