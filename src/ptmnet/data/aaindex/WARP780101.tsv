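# WARP780101	Average interactions per side chain atom (Warme-Morgan, 1978)
A	10.04
C	8.89
D	5.76
E	5.37
F	7.98
G	7.99
H	7.49
I	8.72
K	4.4
L	8.79
M	9.15
N	5.63
P	7.79
Q	5.41
R	6.18
S	7.08
T	7
V	8.88
W	8.07
Y	6.9
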