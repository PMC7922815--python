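compound,threshold_ug_per_l,matrix,source
Pyrazine,300000,53% ethanol/water,website
2M,30000,53% ethanol/water,website
26DM,791,53% ethanol/water,literature
TM2YM,267946,53% ethanol/water,this-study
23DM,965,53% ethanol/water,this-study
2356TTM,80100,53% ethanol/water,literature
235TM,730,53% ethanol/water,literature
2A3M,415,53% ethanol/water,this-study
2E6M,40,53% ethanol/water,literature
2E3M,297,53% ethanol/water,this-study
2E35DM,7.5,53% ethanol/water,literature
5E23DM,530,53% ethanol/water,website
26DE,296,53% ethanol/water,this-study
23DE,172,53% ethanol/water,literature
23DE5M,18,53% ethanol/water,this-study
2I3M,130,53% ethanol/water,website
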