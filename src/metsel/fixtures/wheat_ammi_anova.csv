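source,df,ss,ms,f,p,proportion,accumulated
ENV,5,0.809,0.162,62.000,0.0000,,
REP(ENV),12,0.031,0.003,0.962,0.4870,,
GEN,19,2.230,0.117,43.200,0.0000,,
GEN:ENV,95,2.060,0.022,8.000,0.0000,,
IPC1,23,1.380,0.060,22.100,0.0000,66.80,66.80
IPC2,21,0.523,0.025,9.170,0.0000,25.30,92.20
IPC3,19,0.160,0.008,3.100,0.0000,7.70,99.90
IPC4,17,0.001,0.000,0.030,1.0000,0.10,100.00
IPC5,15,0.000,0.000,0.000,1.0000,0.00,100.00
Residuals,228,0.619,0.003,,,,
Total,454,7.810,0.017,,,,
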