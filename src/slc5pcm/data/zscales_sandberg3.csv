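amino_acid,z1,z2,z3
A,0.24,-2.32,0.60
R,3.52,2.50,-3.50
N,3.05,1.62,1.04
D,3.98,0.93,1.93
C,0.84,-1.67,3.71
Q,1.75,0.50,-1.44
E,3.11,0.26,-0.11
G,2.05,-4.06,0.36
H,2.47,1.95,0.26
I,-3.89,-1.73,-1.71
L,-4.28,-1.30,-1.49
K,2.29,0.89,-2.49
M,-2.85,-0.22,0.47
F,-4.22,1.94,1.06
P,-1.66,0.27,1.84
S,2.39,-1.07,1.15
T,0.75,-2.18,-1.12
W,-4.36,3.94,0.59
Y,-2.54,2.44,0.43
V,-2.59,-2.64,-1.54
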