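patient,CO,OO,ABFG,ABFL,ADFG,ADFL
1,1,1,1,1,1,1
2,1,1,1,0,1,1
3,1,1,0,0,1,0
4,0,0,0,0,X,X
5,1,1,X,X,X,X
6,1,1,0,0,1,1
7,1,1,0,0,X,X
8,0,0,0,0,1,1
9,1,0,1,1,1,1
10,1,1,X,X,1,1
11,0,0,X,X,1,1
12,0,0,1,1,1,1
13,0,0,X,X,1,1
14,1,1,0,X,1,1
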