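# BIOV880102	Information value for accessibility; average fraction 23% (Biou et al., 1988)
A	44
C	90
D	-91
E	-139
F	148
G	-8
H	47
I	100
K	-188
L	108
M	121
N	-72
P	-36
Q	-117
R	-68
S	-60
T	-54
V	117
W	163
Y	22
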