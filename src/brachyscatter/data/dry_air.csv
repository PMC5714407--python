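energy_MeV,mu_rho,muen_rho,f_pe,f_compton,f_rayleigh
0.001,3606,3599,0.998059,1.65719e-06,0.00193956
0.0015,1191,1188,0.997481,1.00155e-05,0.00250891
0.002,527.9,526.2,0.99678,3.75873e-05,0.00318287
0.003,162.5,161.4,0.99323,0.000218947,0.00655155
0.004,77.88,76.36,0.980478,0.00065736,0.0188649
0.005,40.27,39.31,0.976146,0.00160744,0.022247
0.006,23.41,22.7,0.969633,0.00333902,0.0270281
0.008,9.921,9.446,0.951968,0.0101661,0.037866
0.01,5.12,4.742,0.925741,0.0229376,0.0513209
0.015,1.614,1.334,0.824095,0.087856,0.0880491
0.02,0.7779,0.5389,0.685617,0.198209,0.116174
0.03,0.3538,0.1537,0.410386,0.461962,0.127652
0.04,0.2485,0.06833,0.230489,0.665072,0.104439
0.05,0.208,0.04098,0.133818,0.783084,0.083098
0.06,0.1875,0.03041,0.0823331,0.85287,0.0647973
0.08,0.1662,0.02407,0.0368844,0.921562,0.0415536
0.1,0.1541,0.02325,0.0195543,0.951584,0.028862
0.15,0.1356,0.02496,0.00641829,0.978474,0.0151075
0.2,0.1233,0.02672,0.00230503,0.990987,0.00670822
0.3,0.1067,0.02872,0.000655931,0.995756,0.0035881
0.4,0.09549,0.02949,0.000161605,0.996899,0.00293916
0.5,0.08712,0.02966,0,0.997744,0.00225642
0.6,0.08055,0.02953,0,0.998258,0.0017418
0.8,0.07074,0.02882,0,0.99843,0.00157023
1,0.06358,0.02789,0,0.99857,0.00142957
1.25,0.05687,0.02666,0,0.998051,0.00194949
1.5,0.05175,0.02547,0,0.996635,0.00336512
2,0.04447,0.02345,0.00214615,0.989331,0.00852335
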