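# BIOV880101	Information value for accessibility; average fraction 35% (Biou et al., 1988)
A	16
C	168
D	-78
E	-106
F	189
G	-13
H	50
I	151
K	-141
L	145
M	124
N	-74
P	-20
Q	-73
R	-70
S	-70
T	-38
V	123
W	145
Y	53
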