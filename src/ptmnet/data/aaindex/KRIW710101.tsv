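# KRIW710101	Side chain interaction parameter (Krigbaum-Rubin, 1971)
A	4.6
C	-1
D	5.7
E	5.6
F	3.2
G	7.6
H	4.5
I	2.6
K	7.9
L	3.25
M	1.4
N	5.9
P	7
Q	6.1
R	6.5
S	5.25
T	4.8
V	3.4
W	4
Y	4.35
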