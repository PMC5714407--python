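energy_MeV,mu_rho,muen_rho,f_pe,f_compton,f_rayleigh
0.001,4078,4065,0.996812,1.62966e-06,0.00318621
0.0015,1376,1372,0.997093,9.64081e-06,0.00289736
0.002,617.3,615.2,0.996598,3.57474e-05,0.0033663
0.003,192.9,191.7,0.993778,0.00020512,0.00601691
0.004,82.78,81.91,0.989485,0.000687783,0.00982729
0.005,42.58,41.88,0.983544,0.00169067,0.0147652
0.006,24.64,24.05,0.976015,0.00352799,0.0204572
0.008,10.37,9.915,0.95596,0.0108162,0.033224
0.01,5.329,4.944,0.927294,0.0245087,0.0481974
0.015,1.673,1.374,0.818679,0.0942598,0.0870607
0.02,0.8096,0.5503,0.672083,0.211799,0.116118
0.03,0.3756,0.1557,0.389353,0.483934,0.126713
0.04,0.2683,0.06947,0.213109,0.685049,0.101842
0.05,0.2269,0.04223,0.121685,0.798334,0.0799808
0.06,0.2059,0.0319,0.0740598,0.863724,0.0622164
0.08,0.1837,0.02597,0.0327652,0.927244,0.0399913
0.1,0.1707,0.02546,0.0173088,0.955352,0.0273391
0.15,0.1505,0.02764,0.0056455,0.980438,0.0139169
0.2,0.137,0.02967,0.00197458,0.991877,0.00614856
0.3,0.1186,0.03192,0.000489547,0.996277,0.00323358
0.4,0.1061,0.03279,0.000104278,0.997795,0.00210107
0.5,0.09687,0.03299,0,0.997918,0.00208188
0.6,0.08956,0.03284,0,0.998485,0.00151453
0.8,0.07865,0.03206,0,0.998691,0.00130874
1,0.07072,0.03103,0,0.9984,0.00160045
1.25,0.06323,0.02965,0,0.998297,0.00170253
1.5,0.05754,0.02833,0,0.996837,0.00316339
2,0.04942,0.02608,0.00216876,0.990041,0.00779022
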