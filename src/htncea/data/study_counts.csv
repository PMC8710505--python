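symbol,origin,destination,count
0_0.5,normotension,prehypertension,5
0_1,normotension,L1,5
0_2,normotension,L2,1
0.5_0,prehypertension,normotension,12
0.5_0.5,prehypertension,prehypertension,269
0.5_1,prehypertension,L1,101
0.5_2,prehypertension,L2,14
0.5_3,prehypertension,L3,4
1_0,L1,normotension,17
1_0.5,L1,prehypertension,383
1_1,L1,L1,234
1_2,L1,L2,18
1_3,L1,L3,4
2_0,L2,normotension,6
2_0.5,L2,prehypertension,56
2_1,L2,L1,71
2_2,L2,L2,14
2_3,L2,L3,2
3_0.5,L3,prehypertension,15
3_1,L3,L1,15
3_2,L3,L2,2
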