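compound,GT,WZJ,ZY,QHZ,DYT,XJ,LJ,ZJ,WL,FM,ZZY
Pyrazine,4.08,2.1,3.66,5.02,1.45,1.06,0.67,2.23,4.11,3.8,4.5
2M,1.17,3.64,0.65,0.59,1.97,2.2,5.41,3.41,3.09,2.16,1.97
26DM,3.24,1.97,3.96,6.09,0.88,1.28,0.69,0.47,2.78,4.6,1.06
TM2YM,1.76,2.89,3.37,1.92,6.17,3.06,2.71,4.32,3.66,2.79,1.78
23DM,3.96,2.24,2.09,1.88,3.62,3.84,0.77,2.6,4.78,3.5,0.88
2356TTM,7.09,1.02,0.56,1.70,0.79,4.41,4.27,2.28,4.04,2.19,4.78
235TM,0.71,1.37,1.05,1.36,5.81,5.52,0.83,1.27,3.74,1.53,4.24
2A3M,3.5,0.57,2.97,4.43,5.09,1.76,1.69,3.56,1.86,3.71,3.55
2E6M,2.04,1.45,0.54,4.15,6.20,0.63,6.02,0.57,7.64,2.3,5.29
2E3M,0.74,0.62,2.51,4.28,4.2,3.79,2.09,4.92,0.79,0.33,2.81
2E35DM,2.04,2.55,0.76,1.68,3.96,4.65,0.77,2.14,3.01,4.18,4.21
5E23DM,4.22,1.09,0.41,1.56,2.8,4.55,3.09,2.47,0.85,2.76,3.09
26DE,2.19,3.44,1.09,0.77,2.59,6.78,4.58,3.92,2.06,3.9,2.77
23DE,3.9,4.83,5.24,2.88,1.89,3.06,4.71,2.09,5.11,4.3,3.11
23DE5M,2.81,1.97,3.35,6.09,1.44,3.79,4.29,3.09,6.5,3.72,1.03
2I3M,5.09,2.78,1.83,1.09,4.62,3.7,2.88,6.47,4.55,3.29,2.74
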