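compound,bundle,stock_ug_per_l
26DM,supra,1110
2E6M,supra,250
235TM,supra,950
2E35DM,supra,150
23DM,sub,290
23DE,sub,100
23DE5M,sub,11
2A3M,sub,120
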