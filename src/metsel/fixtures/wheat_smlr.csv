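genotype,DH,TKW,CT,Pn,GY,pred,pred_error,rel_error,accuracy,prior_group,posterior_group,cv_posterior_group
G01,0.944,0.821,1.095,0.823,0.755,0.770,-0.015,-0.020,98.013,T,T,HS
G02,0.963,0.833,1.137,0.846,0.800,0.794,0.006,0.007,99.270,HT,HT,T
G03,0.959,0.782,1.172,0.867,0.811,0.810,0.001,0.001,99.900,HT,HT,HT
G04,0.972,0.843,1.150,0.870,0.825,0.811,0.014,0.017,98.278,T,HT,HT
G05,0.950,0.841,1.115,0.801,0.722,0.773,-0.051,-0.071,92.884,HT,HT,HT
G06,0.975,0.796,1.112,0.763,0.673,0.681,-0.008,-0.012,98.798,S,S,S
G07,0.955,0.749,1.188,0.766,0.789,0.748,0.041,0.052,94.848,HT,T,T
G08,0.942,0.816,1.165,0.769,0.790,0.792,-0.001,-0.002,99.810,S,S,S
G09,0.960,0.836,1.162,0.669,0.693,0.709,-0.016,-0.023,97.695,HT,HT,HS
G10,0.952,0.791,1.167,0.877,0.868,0.830,0.038,0.044,95.613,T,T,S
G11,0.955,0.794,1.157,0.871,0.839,0.815,0.024,0.029,97.107,HS,HS,HS
G12,0.957,0.766,1.143,0.764,0.684,0.718,-0.034,-0.050,95.021,HS,S,S
G13,0.943,0.802,1.113,0.636,0.689,0.658,0.031,0.046,95.435,HS,HS,HS
G14,0.956,0.808,1.122,0.700,0.720,0.687,0.033,0.046,95.419,T,T,S
G15,0.972,0.727,1.088,0.747,0.579,0.617,-0.038,-0.065,93.502,M,M,S
G16,0.934,0.825,1.097,0.834,0.769,0.796,-0.027,-0.035,96.496,T,T,HS
G17,0.951,0.822,1.033,0.836,0.770,0.718,0.053,0.068,93.181,HS,T,T
G18,0.956,0.811,1.200,0.776,0.795,0.799,-0.004,-0.005,99.479,M,M,HT
G19,0.963,0.752,1.082,0.747,0.625,0.641,-0.016,-0.026,97.413,S,S,M
G20,0.939,0.821,1.207,0.913,0.894,0.923,-0.030,-0.033,96.694,S,T,T
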