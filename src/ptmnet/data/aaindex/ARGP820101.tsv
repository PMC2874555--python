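# ARGP820101	Hydrophobicity index (Argos et al., 1982)
A	0.61
C	1.07
D	0.46
E	0.47
F	2.02
G	0.07
H	0.61
I	2.22
K	1.15
L	1.53
M	1.18
N	0.06
P	1.95
Q	0
R	0.6
S	0.05
T	0.05
V	1.32
W	2.65
Y	1.88
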