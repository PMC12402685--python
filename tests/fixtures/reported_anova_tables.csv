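accent,factor,component,effect,df1,df2,mse,F,pes,p_text
L1,F1,N400,Constraint,1,41,2.58,145.58,0.780,<0.001
L1,F1,N400,Face,1,41,1.52,15.38,0.273,<0.001
L1,F1,N400,Constraint*Face,1,41,1.12,3.74,0.084,0.060
L1,F2,P2,Constraint,1,41,1.21,19.57,0.323,<0.001
L1,F2,P2,Face,1,41,1.62,2.97,0.068,0.092
L1,F2,P2,Constraint*Face,1,41,1.59,0.45,0.011,0.507
L1,F3,P2,Constraint,1,41,1.11,0.08,0.002,0.779
L1,F3,P2,Face,1,41,1.16,2.23,0.052,0.143
L1,F3,P2,Constraint*Face,1,41,1.50,0.02,,0.878
L1,F4,Slow wave,Constraint,1,41,2.99,25.31,0.382,<0.001
L1,F4,Slow wave,Face,1,41,1.08,0.22,0.005,0.642
L1,F4,Slow wave,Constraint*Face,1,41,0.71,0.01,,0.937
L1,F5,N400,Constraint,1,41,1.66,100.07,0.709,<0.001
L1,F5,N400,Face,1,41,1.49,2.21,0.051,0.145
L1,F5,N400,Constraint*Face,1,41,1.12,0.15,0.004,0.696
L1,F6,P3b,Constraint,1,41,2.05,65.09,0.614,<0.001
L1,F6,P3b,Face,1,41,1.52,6.73,0.141,0.013
L1,F6,P3b,Constraint*Face,1,41,0.94,8.19,0.166,0.007
L1,F7,P3b,Constraint,1,41,2.00,53.71,0.567,<0.001
L1,F7,P3b,Face,1,41,1.14,4.42,0.097,0.042
L1,F7,P3b,Constraint*Face,1,41,1.50,7.41,0.153,0.009
L1,F8,Slow wave,Constraint,1,41,2.26,12.75,0.237,<0.001
L1,F8,Slow wave,Face,1,41,0.87,0.65,0.016,0.426
L1,F8,Slow wave,Constraint*Face,1,41,0.92,0.04,,0.843
L1,F9,N1,Constraint,1,41,1.00,0.11,0.003,0.740
L1,F9,N1,Face,1,41,1.67,2.66,0.061,0.110
L1,F9,N1,Constraint*Face,1,41,0.82,0.38,0.009,0.540
L2,F1,P2,Constraint,1,41,2.66,22.63,0.356,<0.001
L2,F1,P2,Face,1,41,1.51,3.35,0.076,0.074
L2,F1,P2,Constraint*Face,1,41,1.86,0.09,0.002,0.760
L2,F2,Slow wave,Constraint,1,41,4.35,148.95,0.784,<0.001
L2,F2,Slow wave,Face,1,41,2.06,0.00,,0.991
L2,F2,Slow wave,Constraint*Face,1,41,1.41,3.76,0.084,0.059
L2,F3,Slow wave,Constraint,1,41,2.26,91.20,0.690,<0.001
L2,F3,Slow wave,Face,1,41,0.83,0.02,,0.901
L2,F3,Slow wave,Constraint*Face,1,41,0.88,0.09,0.002,0.770
L2,F4,N400,Constraint,1,41,4.06,56.96,0.581,<0.001
L2,F4,N400,Face,1,41,1.85,11.39,0.217,0.002
L2,F4,N400,Constraint*Face,1,41,0.82,0.88,0.021,0.353
L2,F5,P3a,Constraint,1,41,2.51,0.71,0.017,0.405
L2,F5,P3a,Face,1,41,1.16,9.18,0.183,0.004
L2,F5,P3a,Constraint*Face,1,41,1.35,0.29,0.007,0.590
L2,F6,P3a,Constraint,1,41,1.64,25.78,0.386,<0.001
L2,F6,P3a,Face,1,41,0.89,3.18,0.072,0.082
L2,F6,P3a,Constraint*Face,1,41,1.07,0.14,0.003,0.710
L2,F7,N400,Constraint,1,41,2.61,93.03,0.694,<0.001
L2,F7,N400,Face,1,41,1.33,5.90,0.126,0.020
L2,F7,N400,Constraint*Face,1,41,1.33,0.69,0.016,0.413
L2,F8,Slow wave,Constraint,1,41,1.67,30.24,0.424,<0.001
L2,F8,Slow wave,Face,1,41,1.02,0.01,,0.932
L2,F8,Slow wave,Constraint*Face,1,41,1.40,1.59,0.037,0.214
L2,F9,Early negativity,Constraint,1,41,1.36,16.97,0.293,<0.001
L2,F9,Early negativity,Face,1,41,1.18,0.08,0.002,0.775
L2,F9,Early negativity,Constraint*Face,1,41,1.45,2.64,0.060,0.112
L2,F10,N1,Constraint,1,41,1.24,3.76,0.084,0.059
L2,F10,N1,Face,1,41,1.39,5.84,0.125,0.020
L2,F10,N1,Constraint*Face,1,41,1.23,2.99,0.068,0.091
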