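# LAWE840101	Transfer free energy, CHP/water (Lawson et al., 1984)
A	-0.48
C	-0.32
D	-0.75
E	-0.71
F	1.03
G	0
H	-0.51
I	0.81
K	-0.09
L	1.02
M	0.81
N	-0.87
P	2.03
Q	-0.32
R	-0.06
S	0.05
T	-0.35
V	0.56
W	0.66
Y	1.24
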