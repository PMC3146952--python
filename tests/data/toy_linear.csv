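cluster_id,unit_id,time,A,y
0,0,0,1,0.3
0,1,0,0,0.5
1,0,0,0,-0.2
1,1,0,1,0.1
2,0,0,1,0.8
2,1,0,0,0.2
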