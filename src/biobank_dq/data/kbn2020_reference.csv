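institution,total_count,error_count,warning_count,completeness,validity,accuracy,uniqueness
A,1466,745,721,721,745,0,0
B,440,22,418,0,21,419,0
C,9102,233,8869,2220,387,6495,0
D,2256,147,2109,62,148,2046,0
E,4714,4712,2,1,4669,31,13
F,13093,8320,4773,2772,9957,71,293
G,238,6,232,232,6,0,0
H,2045,775,1270,0,230,1285,530
I,3190,3165,25,23,3163,4,0
J,242,236,6,6,235,1,0
K,38,35,3,20,16,2,0
L,1461,209,1252,21,210,1208,22
M,0,0,0,0,0,0,0
N,2540,59,2481,2479,61,0,0
O,1890,1757,133,124,1741,24,1
P,114,30,84,81,15,18,0
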