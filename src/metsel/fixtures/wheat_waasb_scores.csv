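side,code,Y,IPC1,IPC2,IPC3,IPC4,IPC5,waasb,rank
genotype,G01,0.755,-0.021,0.037,-0.109,-0.006,-0.025,0.032,1
genotype,G02,0.800,0.261,0.149,0.132,-0.011,0.000,0.223,19
genotype,G03,0.811,0.018,-0.233,0.056,-0.018,0.015,0.075,4
genotype,G04,0.825,0.286,0.050,0.039,0.035,-0.019,0.207,17
genotype,G05,0.722,-0.122,0.114,-0.040,-0.015,0.013,0.114,7
genotype,G06,0.673,-0.014,0.160,-0.048,-0.001,0.001,0.054,2
genotype,G07,0.789,-0.280,-0.105,-0.082,0.003,-0.018,0.221,18
genotype,G08,0.790,-0.248,0.154,0.328,0.015,0.011,0.231,20
genotype,G09,0.693,-0.229,0.147,-0.038,-0.012,0.018,0.194,15
genotype,G10,0.868,-0.180,-0.324,-0.021,-0.024,0.007,0.204,16
genotype,G11,0.839,0.060,-0.215,0.106,-0.012,-0.016,0.103,6
genotype,G12,0.684,-0.043,0.132,0.023,0.009,0.009,0.064,3
genotype,G13,0.689,0.222,0.074,-0.108,0.021,-0.008,0.176,13
genotype,G14,0.720,0.160,-0.167,-0.006,0.020,0.055,0.150,10
genotype,G15,0.579,0.135,0.101,-0.057,-0.121,-0.001,0.120,8
genotype,G16,0.769,0.219,-0.103,0.007,0.028,-0.003,0.173,12
genotype,G17,0.770,0.252,-0.016,-0.041,0.015,-0.003,0.176,14
genotype,G18,0.794,-0.125,0.055,0.030,0.013,-0.009,0.100,5
genotype,G19,0.625,-0.179,0.084,-0.214,0.045,0.016,0.158,11
genotype,G20,0.894,-0.171,-0.093,0.041,0.013,-0.042,0.141,9
environment,E1,0.733,0.318,0.219,0.309,-0.005,0.035,0.292,4
environment,E2,0.837,-0.239,0.416,-0.208,-0.057,-0.002,0.281,3
environment,E3,0.774,0.346,-0.286,-0.257,-0.006,0.036,0.324,5
environment,E4,0.678,-0.426,-0.337,0.160,-0.063,-0.004,0.383,6
environment,E5,0.751,0.331,-0.028,0.013,0.010,-0.072,0.230,2
environment,E6,0.753,-0.331,0.017,-0.016,0.121,0.006,0.227,1
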