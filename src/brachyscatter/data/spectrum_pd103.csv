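energy_MeV,probability
0.020074,0.224
0.020216,0.423
0.022717,0.1040
0.023312,0.0194
0.039748,0.000683
0.357450,0.000221
0.497080,0.0000395
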