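test,23DM,2A3M,23DE,23DE5M,26DM,235TM,2E6M,2E35DM,difference_observed
1,1,0,0,0,0,0,0,0,ns
2,0,1,0,0,0,0,0,0,ns
3,0,0,1,0,0,0,0,0,ns
4,0,0,0,1,0,0,0,0,ns
5,0,0,0,0,1,0,0,0,ns
6,0,0,0,0,0,1,0,0,ns
7,0,0,0,0,0,0,1,0,ns
8,0,0,0,0,0,0,0,1,ns
9,0,0,0,0,1,1,1,1,**
10,1,1,1,1,1,1,1,1,***
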