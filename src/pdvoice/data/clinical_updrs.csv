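ID,Gender,Age,III Total ON,III Total OFF,III.I ON,III.I OFF
1,F,53,26,39,2,2
2,F,62,18,34,1,2
3,F,68,8,15,1,1
4,F,67,21,40,0,1
5,M,73,18,26,1,2
6,F,68,4,10,0,0
7,M,73,34,50,2,3
8,M,74,31,53,3,4
9,F,55,28,36,1,1
10,M,66,19,35,3,4
11,F,70,6,14,0,1
12,F,76,28,39,1,2
13,M,66,11,21,0,1
14,M,70,41,48,3,4
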