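# BULH740101	Transfer free energy to surface (Bull-Breese, 1974)
A	-0.2
C	-0.45
D	-0.2
E	-0.3
F	-2.33
G	0
H	-0.12
I	-2.26
K	-0.35
L	-2.46
M	-1.47
N	0.08
P	-0.98
Q	0.16
R	-0.12
S	-0.39
T	-0.52
V	-1.56
W	-2.01
Y	-2.24
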