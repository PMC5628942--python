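percent,BB,SF,NE,MV,SH
1,9,13,2,19,21
2,11,15,4,23,27
5,14,21,6,28,33
10,18,26,10,33,37
50,39,46,27,48,53
75,49,53,42,54,57
90,56,57,53,58,59
100,60,60,60,60,60
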