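residue	max_total_sasa	max_sidechain_sasa
A	129.0	55.0
C	167.0	93.0
D	193.0	119.0
E	223.0	149.0
F	240.0	166.0
G	104.0	30.0
H	224.0	150.0
I	197.0	123.0
K	236.0	162.0
L	201.0	127.0
M	224.0	150.0
N	195.0	121.0
P	159.0	85.0
Q	225.0	151.0
R	274.0	200.0
S	155.0	81.0
T	172.0	98.0
V	174.0	100.0
W	285.0	211.0
Y	263.0	189.0
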