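trial,action,reward,phase
0,R,0,forced
1,R,0,forced
2,R,0,forced
3,R,1,forced
4,R,0,forced
5,R,0,forced
6,R,1,forced
7,R,0,forced
8,R,0,forced
9,R,0,forced
10,L,0,forced
11,L,0,forced
12,L,0,forced
13,L,0,forced
14,L,0,forced
15,L,1,forced
16,L,0,forced
17,L,0,forced
18,L,0,forced
19,L,0,forced
20,L,0,forced
21,L,0,forced
22,L,0,forced
23,L,0,forced
24,L,0,forced
25,L,0,forced
26,L,0,forced
27,L,0,forced
28,L,0,forced
29,L,0,forced
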