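compound,GT,WZJ,ZY,QHZ,DYT,XJ,LJ,ZJ,WL,FM,ZZY
Pyrazine,82.11,192.41,85.25,176.21,196.79,193.92,71.14,117.55,99.8,73.08,29.81
2M,135.21,110.54,148.2,195.29,159.41,115.33,62.15,36.02,71.56,56.88,51.06
26DM,1257.48,992.28,1497.57,1116.28,1054.61,951.06,735.28,1589.16,878.3,459.48,618.19
TM2YM,6.51,74.7,53.07,54.1,25.4,39.28,7.05,17.33,10.54,18.14,10.92
23DM,312.01,175.8,682.51,290.8,195.26,315.7,112.66,295.3,237.4,125.89,167.2
2356TTM,1861.98,1634.52,805.19,1208.3,895.22,1183.12,474.99,1609.47,601.51,693.42,886.07
235TM,1086.25,1328.06,866.33,950.19,760.57,906.55,440.1,1754.48,497.11,316.52,513.97
2A3M,236.75,156.34,79.26,125.41,196.22,261.07,78.15,56.12,65.4,72.3,49.49
2E6M,428.24,330.72,502.11,255.9,420.85,369.26,361.98,690.69,400.24,336.76,293.25
2E3M,8.19,19.33,6.49,23.1,19.84,7.11,6.19,46.19,5.1,6.71,2.65
2E35DM,389.85,294.45,240.44,153.61,486.49,251.42,100.23,521.57,112.3,83.75,95.1
5E23DM,1.83,6.42,1.64,2.04,5.68,12.52,1.01,1.64,0.83,1.75,1.23
26DE,25.33,39.57,31.09,11.75,43.21,52.41,75.21,17.08,12,17.63,15.33
23DE,159.15,240.14,125.61,107.55,167.61,110.9,64.8,97.14,62.4,78.6,28.08
23DE5M,13.76,10.54,15.47,11.86,4.5,6.69,4.39,2.71,4.16,1.7,1.09
2I3M,2.31,5.87,4.25,4.25,1.33,1.41,3.82,0.96,1.14,1.92,3.18
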