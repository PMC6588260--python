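trial,action,reward,phase
0,R,0,forced
1,R,0,forced
2,R,0,forced
3,R,0,forced
4,R,0,forced
5,R,0,forced
6,L,0,forced
7,R,0,forced
8,L,0,forced
9,,0,on
10,,0,on
11,,0,on
12,,0,on
13,,0,on
14,,0,on
15,,0,on
16,,0,on
17,,0,on
18,,0,on
19,,0,on
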