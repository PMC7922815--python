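number,compound,retention_time_min,rt_sd_min,precursor_mz,quantifier_mz,quantifier_cone_v,quantifier_ce_ev,confirmation_mz,confirmation_cone_v,confirmation_ce_ev
1,Pyrazine,1.77,0.03,80.7,54.1,35,14,41.2,37,16
2,2M,3.35,0.03,94.7,68.0,33,14,54.3,33,16
3,26DM,6.45,0.05,108.9,41.5,31,19,67.7,33,18
4,TM2YM,7.05,0.04,152.7,53.2,7,22,94.1,9,22
5,23DM,7.41,0.06,108.9,41.5,31,19,67.7,33,18
6,2356TTM,8.41,0.04,137.0,55.3,31,21,42.1,31,24
7,235TM,9.75,0.03,123.0,82.2,33,17,42.0,33,20
8,2A3M,14.00,0.07,136.8,109.1,17,16,94.5,17,18
9,2E6M,15.43,0.06,123.0,108.2,27,19,81.5,29,19
10,2E3M,16.29,0.08,123.0,108.2,27,19,81.5,29,19
11,2E35DM,18.76,0.04,137.0,121.4,29,17,80.4,30,19
12,5E23DM,19.49,0.06,137.0,121.4,29,17,80.4,30,19
13,26DE,25.48,0.06,136.8,121.8,33,20,108.4,33,22
14,23DE,26.26,0.09,136.8,121.8,33,20,108.4,33,22
15,23DE5M,29.43,0.04,150.8,136.0,35,16,122.5,35,18
16,2I3M,32.64,0.03,151.0,108.0,29,26,135.8,28,23
17,2-Propylpyrazine (IS),20.73,0.05,122.7,108.0,23,16,61.1,23,18
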