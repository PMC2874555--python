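# HOPA770101	Hydration number (Hopfinger, 1971), Cited by Charton-Charton (1982)
A	1
C	0.1
D	6.5
E	6.2
F	1.4
G	1.1
H	2.8
I	0.8
K	5.3
L	0.8
M	0.7
N	2.2
P	0.9
Q	2.1
R	2.3
S	1.7
T	1.5
V	0.9
W	1.9
Y	2.1
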