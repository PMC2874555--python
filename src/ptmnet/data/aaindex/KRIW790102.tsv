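# KRIW790102	Fraction of site occupied by water (Krigbaum-Komoriya, 1979)
A	0.28
C	0.11
D	0.33
E	0.37
F	0.1
G	0.28
H	0.23
I	0.12
K	0.59
L	0.16
M	0.08
N	0.31
P	0.46
Q	0.39
R	0.34
S	0.27
T	0.26
V	0.22
W	0.15
Y	0.25
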