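,A,G,V,L,I,P,F,M,W,C,D,E,R,K,H,N,Q,S,T,Y
A,6,,,,,,,,,,,,,,,,,,,
G,3,7,,,,,,,,,,,,,,,,,,
V,5,7,3,,,,,,,,,,,,,,,,,
L,5,8,4,4,,,,,,,,,,,,,,,,
I,3,4,3,4,6,,,,,,,,,,,,,,,
P,2,2,2,2,5,1,,,,,,,,,,,,,,
F,8,6,4,8,6,4,7,,,,,,,,,,,,,
M,7,8,5,8,5,4,6,8,,,,,,,,,,,,
W,9,9,9,12,11,11,14,14,15,,,,,,,,,,,
C,7,10,4,4,8,9,6,8,8,5,,,,,,,,,,
D,21,23,22,21,21,11,20,27,26,30,67,,,,,,,,,
E,22,21,21,22,21,15,22,27,11,29,68,78,,,,,,,,
R,22,21,27,26,25,27,23,24,30,19,132,138,41,,,,,,,
K,21,23,23,26,25,29,31,6,39,22,138,149,45,43,,,,,,
H,11,9,-9,-9,8,10,13,14,18,11,29,30,30,29,15,,,,,
N,11,14,11,10,9,6,12,14,15,13,22,25,19,24,16,18,,,,
Q,12,12,11,11,10,11,13,12,12,12,37,30,31,30,15,19,23,,,
S,11,14,9,9,6,3,13,9,16,7,39,34,22,23,14,13,18,13,,
T,10,12,6,10,6,3,12,8,12,11,39,39,19,22,17,13,18,12,10,
Y,10,11,7,7,5,9,10,12,11,10,25,24,35,29,14,10,19,11,10,12
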