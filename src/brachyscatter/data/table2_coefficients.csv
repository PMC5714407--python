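isotope,label,a0,a1,a2,a3,a4,a5,a6,r_min,r_max
Ir192,(28+2),1.009,-2.976e-2,3.632e-2,-1.476e-2,-1.026e-3,0,0,0.25,2
Ir192,(26+4),1.007,-4.012e-2,6.844e-2,-4.830e-2,1.431e-2,-1.564e-3,0,0.25,4
Ir192,(25+5),1.005,-2.917e-2,4.338e-2,-2.585e-2,6.332e-3,-5.685e-4,0,0.25,5
Ir192,(24+6),9.982e-1,3.291e-3,-6.178e-3,5.870e-3,-2.812e-3,5.666e-4,-4.179e-5,0.25,6
Ir192,(22+8),9.973e-1,8.083e-3,-1.025e-2,5.884e-3,-1.737e-3,2.370e-4,-1.230e-5,0.25,8
Pd103,(28+2),1.003,-4.518e-3,9.935e-3,-7.712e-3,-2.711e-4,0,0,0.25,2
Pd103,(26+4),9.985e-1,7.622e-3,-1.125e-2,6.065e-3,-1.098e-3,0,0,0.25,4
Pd103,(25+5),9.976e-1,1.043e-2,-1.202e-2,5.117e-3,-7.043e-4,0,0,0.25,5
Pd103,(24+6),9.978e-1,1.266e-2,-2.361e-2,1.897e-2,-7.329e-3,1.344e-3,-9.413e-5,0.25,6
Pd103,(22+8),9.963e-1,1.745e-2,-2.429e-2,1.420e-2,-3.955e-3,5.202e-4,-2.600e-5,0.25,8
Cs137,(28+2),1.013,-4.767e-2,5.188e-2,-1.811e-2,0,0,0,0.25,2
Cs137,(26+4),9.888e-1,6.047e-2,-1.100e-1,9.290e-2,-4.031e-2,8.560e-3,-7.091e-4,0.25,4
Cs137,(25+5),9.971e-1,1.511e-2,-2.354e-2,1.629e-2,-5.977e-3,1.081e-3,-7.777e-5,0.25,5
Cs137,(24+6),9.994e-1,3.193e-2,-3.879e-2,1.644e-3,-4.362e-4,6.241e-5,-4.568e-6,0.25,6
Cs137,(22+8),9.943e-1,2.180e-2,-2.545e-2,1.269e-2,-3.099e-3,3.585e-4,-1.591e-5,0.25,8
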