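energy_MeV,probability
0.061486,0.0120
0.063000,0.0205
0.065122,0.0263
0.066831,0.0446
0.071079,0.0024
0.075368,0.0053
0.075749,0.0102
0.136343,0.00199
0.201311,0.00473
0.205795,0.0334
0.283267,0.00266
0.295957,0.2871
0.308455,0.2970
0.316506,0.8286
0.374485,0.00727
0.416469,0.00670
0.468069,0.4784
0.484575,0.0319
0.489060,0.00438
0.588581,0.0452
0.604411,0.0820
0.612462,0.0534
0.884537,0.00291
1.061480,0.00053
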