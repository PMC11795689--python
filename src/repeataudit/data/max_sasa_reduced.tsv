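residue	max_total_sasa	max_sidechain_sasa
A	159.64	120.76
C	212.05	174.49
D	200.01	161.72
E	200.01	161.72
F	207.89	169.57
G	150.82	120.76
H	201.12	162.95
I	207.89	169.57
K	201.12	162.95
L	207.89	169.57
M	212.05	174.49
N	200.01	161.72
P	207.89	169.57
Q	200.01	161.72
R	201.12	162.95
S	200.01	161.72
T	200.01	161.72
V	207.89	169.57
W	207.89	169.57
Y	207.89	169.57
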