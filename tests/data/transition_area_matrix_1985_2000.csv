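from\to,1,2,3,4,5
1,1237843,15816,854004,86438,7547
2,96349,124925,341910,77682,18411
3,1439380,1302,3391711,40659,22543
4,224941,116193,345128,492394,295
5,21280,8,1560,230,1600
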