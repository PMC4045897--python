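estimator,period,estimate,ci_low,ci_high
LP,1985_11,128.23,82.01,174.45
LP,1986_01,98.75,83.99,113.51
LP,1986_03,108.77,98.18,119.36
LP,1986_11,91.75,74.14,109.36
LP,1987_01,56.11,49.89,62.33
MLP,1985_11,144.91,117.64,172.21
MLP,1986_01,114.03,105.64,122.42
MLP,1986_03,131.52,125.30,137.73
MLP,1986_11,113.09,102.67,123.50
MLP,1987_01,75.25,70.47,80.03
MPE,1985_11,131.19,94.46,167.93
MPE,1986_01,103.27,89.96,116.58
MPE,1986_03,114.35,106.47,122.23
MPE,1986_11,121.22,86.78,155.66
MPE,1987_01,72.00,64.89,79.12
Appropriate,1985_11,115,93,156
Appropriate,1986_01,114,96,151
Appropriate,1986_03,123,110,150
Appropriate,1986_11,89,80,107
Appropriate,1987_01,69,59,96
IntJK,1985_11,155,124,205
IntJK,1986_01,120,102,155
IntJK,1986_03,138,118,178
IntJK,1986_11,97,85,121
IntJK,1987_01,68,59,90
ME,1985_11,145,104,232
ME,1986_01,111,95,149
ME,1986_03,128,111,170
ME,1986_11,91,79,119
ME,1987_01,67,57,95
SC1,1985_11,163.0,117.15,255.15
SC1,1986_01,120.2,99.81,152.76
SC1,1986_03,125.2,112.21,145.04
SC1,1986_11,98.6,86.09,122.96
SC1,1987_01,71.9,60.47,92.32
SC2,1985_11,131.8,98.94,204.51
SC2,1986_01,110.3,93.63,137.48
SC2,1986_03,119.8,107.22,137.58
SC2,1986_11,86.2,76.85,103.10
SC2,1987_01,64.2,54.41,82.27
EE,1985_11,145,107.46,215.22
EE,1986_01,113,96.94,138.09
EE,1986_03,116.2,106.06,130.99
EE,1986_11,91.9,81.79,107.69
EE,1987_01,67.2,57.92,82.05
TruncGeom,1985_11,246,182,347
TruncGeom,1986_01,168,143,200
TruncGeom,1986_03,150,137,165
TruncGeom,1986_11,164,135,204
TruncGeom,1987_01,83,73,96
FiniteMixtures,1985_11,117.51,94.2,161.58
FiniteMixtures,1986_01,96.06,88.06,111.98
FiniteMixtures,1986_03,101.43,98.07,110.24
FiniteMixtures,1986_11,88.83,79.38,107.82
FiniteMixtures,1987_01,55.12,52.29,64.19
GSRUN,1985_11,116.47,93.68,159.49
GSRUN,1986_01,106.88,90.16,151.15
GSRUN,1986_03,109.05,100.11,137.45
GSRUN,1986_11,89.81,80.08,108.93
GSRUN,1987_01,55.33,52.47,63.74
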