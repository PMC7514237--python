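case,X1,X2,X3,X4,X5,X6
FRA1,"[155.00,157.00]","[58.00,61.01]","[100.45,103.28]","[105.00,107.30]","[61.40,65.73]","[64.20,67.80]"
FRA2,"[154.00,160.01]","[57.00,64.00]","[101.98,105.55]","[104.35,107.30]","[60.88,63.03]","[62.94,66.47]"
FRA3,"[154.01,161.00]","[57.00,63.00]","[99.36,105.65]","[101.04,109.04]","[60.95,65.60]","[60.42,66.40]"
HUS1,"[168.9,172.84]","[58.55,63.39]","[102.83,106.53]","[122.38,124.52]","[56.73,61.07]","[60.44,64.54]"
HUS2,"[169.8,175.03]","[60.21,64.38]","[102.94,108.71]","[120.24,124.52]","[56.73,62.37]","[60.44,66.84]"
HUS3,"[168.8,175.15]","[61.4,63.51]","[104.35,107.45]","[120.93,125.18]","[57.2,61.72]","[58.14,67.08]"
INC1,"[155.3,160.45]","[53.15,60.21]","[95.88,98.49]","[91.68,94.37]","[62.48,66.22]","[58.9,63.13]"
INC2,"[156.3,161.31]","[51.09,60.07]","[95.77,99.36]","[91.21,96.83]","[54.92,64.2]","[54.41,61.55]"
INC3,"[154.5,160.31]","[55.08,59.03]","[93.54,98.98]","[90.43,96.43]","[59.03,65.86]","[55.97,65.8]"
ISA1,"[164,168]","[55.01,60.03]","[120.28,123.04]","[117.52,121.02]","[54.38,57.45]","[50.8,53.25]"
ISA2,"[163,170]","[54.04,59]","[118.8,123.04]","[116.67,120.24]","[55.47,58.67]","[52.43,55.23]"
ISA3,"[164,169.01]","[55,59.01]","[117.38,123.11]","[116.67,122.43]","[52.8,58.31]","[52.2,55.47]"
JPL1,"[167.1,171.19]","[61.03,65.01]","[118.23,121.82]","[108.3,111.2]","[63.89,67.88]","[57.28,60.83]"
JPL2,"[169.1,173.18]","[60.07,65.07]","[118.85,120.88]","[108.98,113.17]","[62.63,69.07]","[57.38,61.62]"
JPL3,"[169,170.11]","[59.01,65.01]","[115.88,121.38]","[110.34,112.49]","[61.72,68.25]","[59.46,62.94]"
KHA1,"[149.3,155.54]","[54.15,59.14]","[111.95,115.75]","[105.36,111.07]","[54.2,58.14]","[48.27,50.61]"
KHA2,"[149.3,155.32]","[52.04,58.22]","[111.2,113.22]","[105.36,111.07]","[53.71,58.14]","[49.41,52.8]"
KHA3,"[150.3,157.26]","[52.09,60.21]","[109.04,112.7]","[104.74,111.07]","[55.47,60.03]","[49.2,53.41]"
LOT1,"[152.6,157.62]","[51.35,56.22]","[116.73,119.67]","[114.62,117.41]","[55.44,59.55]","[53.01,56.6]"
LOT2,"[154.6,157.62]","[52.24,56.32]","[117.52,119.67]","[114.28,117.41]","[57.63,60.61]","[54.41,57.98]"
LOT3,"[154.8,157.81]","[50.36,55.23]","[117.59,119.75]","[114.04,116.83]","[56.64,61.07]","[55.23,57.8]"
PHI1,"[163.1,167.07]","[66.03,68.07]","[115.26,119.6]","[116.1,121.02]","[60.96,65.3]","[57.01,59.82]"
PHI2,"[164,168.03]","[65.03,68.12]","[114.55,119.6]","[115.26,120.97]","[60.96,67.27]","[55.32,61.52]"
PHI3,"[161,167]","[64.07,69.01]","[116.67,118.79]","[114.59,118.83]","[61.52,68.68]","[56.57,60.11]"
ROM1,"[167.2,171.24]","[64.07,68.07]","[123.75,126.59]","[122.92,126.37]","[51.22,54.64]","[49.65,53.71]"
ROM2,"[168.2,172.14]","[63.13,68.07]","[122.33,127.29]","[124.08,127.14]","[50.22,57.14]","[49.93,56.94]"
ROM3,"[167.1,171.19]","[63.13,68.03]","[121.62,126.57]","[122.58,127.78]","[49.41,57.28]","[50.99,60.46]"
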