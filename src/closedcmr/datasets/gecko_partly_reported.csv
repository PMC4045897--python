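estimator,period,estimate,ci_low,ci_high
LP,1985_11,131.59,92.29,170.89
LP,1986_01,123.97,105.86,142.09
LP,1986_03,161.1,145.54,176.66
LP,1986_11,139.34,112.42,166.27
LP,1987_01,104.21,88.71,119.71
MLP,1985_11,163.04,131.92,194.16
MLP,1986_01,143.30,132.82,153.78
MLP,1986_03,194.56,185.55,203.57
MLP,1986_11,172.53,155.89,189.18
MLP,1987_01,137.59,126.59,148.59
MPE,1985_11,150.13,109.95,190.30
MPE,1986_01,126.33,111.02,141.63
MPE,1986_03,169.90,158.49,181.31
MPE,1986_11,186.73,129.56,243.89
MPE,1987_01,128.23,112.51,143.95
Appropriate,1985_11,129,106,170
Appropriate,1986_01,151,126,199
Appropriate,1986_03,186,165,224
Appropriate,1986_11,141,119,186
Appropriate,1987_01,134,114,170
IntJK,1985_11,154,132,213
IntJK,1986_01,160,134,204
IntJK,1986_03,207,178,256
IntJK,1986_11,161,137,200
IntJK,1987_01,134,114,170
ME,1985_11,151,114,227
ME,1986_01,146,122,195
ME,1986_03,188,163,235
ME,1986_11,146,123,191
ME,1987_01,124,103,169
SC1,1985_11,171.8,126.87,257.32
SC1,1986_01,159.1,131.96,200.21
SC1,1986_03,191.6,169.59,220.55
SC1,1986_11,158.1,132.70,197.78
SC1,1987_01,139.7,114.37,178.96
SC2,1985_11,137.2,110.36,206.13
SC2,1986_01,146.0,122.22,181.47
SC2,1986_03,180.7,161.17,208.29
SC2,1986_11,133.8,117.95,164.21
SC2,1987_01,119.5,99.79,154.64
EE,1985_11,153.4,116.21,221.12
EE,1986_01,147.6,125.62,177.25
EE,1986_03,177.9,161.07,199.69
EE,1986_11,143.5,124.11,173.4
EE,1987_01,126.3,107.53,155.95
TruncGeom,1985_11,275,207,378
TruncGeom,1986_01,210,181,248
TruncGeom,1986_03,231,212,254
TruncGeom,1986_11,255,212,313
TruncGeom,1987_01,247,207,301
FiniteMixtures,1985_11,140.01,100.28,247.53
FiniteMixtures,1986_01,130.93,115.21,160.92
FiniteMixtures,1986_03,175.89,152.33,235.65
FiniteMixtures,1986_11,134.06,119.03,160.37
FiniteMixtures,1987_01,113.55,97.05,150.92
GSRUN,1985_11,130.2,106.21,173.89
GSRUN,1986_01,136.34,115.58,181.64
GSRUN,1986_03,171.01,146.92,253.56
GSRUN,1986_11,133.75,118.92,159.61
GSRUN,1987_01,111.62,97.05,142.45
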