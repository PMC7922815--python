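compound,concentration_ug_per_l
23DM,180
2A3M,160
23DE,80
23DE5M,12
26DM,800
235TM,770
2E6M,90
2E35DM,300
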