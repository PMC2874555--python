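# KRIW790101	Side chain interaction parameter (Krigbaum-Komoriya, 1979)
A	4.32
C	1.73
D	6.04
E	6.17
F	2.59
G	6.09
H	5.66
I	2.31
K	7.92
L	3.93
M	2.44
N	6.24
P	7.19
Q	6.13
R	6.55
S	5.37
T	5.16
V	3.31
W	2.78
Y	3.58
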