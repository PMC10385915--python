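sex,age_band,from_state,p1,p2,p3,p4,p5,p6
male,60-69,1,0.278,0.212,0.360,0.010,0.107,0.033
male,60-69,2,0.126,0.217,0.320,0.037,0.259,0.040
male,60-69,3,0.155,0.231,0.349,0.022,0.190,0.053
male,60-69,4,0.007,0.044,0.038,0.305,0.599,0.007
male,60-69,5,0.018,0.073,0.074,0.142,0.683,0.010
male,60-69,6,0.000,0.000,0.000,0.000,0.000,1.000
female,60-69,1,0.389,0.223,0.291,0.010,0.077,0.010
female,60-69,2,0.165,0.274,0.350,0.029,0.167,0.015
female,60-69,3,0.169,0.276,0.352,0.027,0.162,0.015
female,60-69,4,0.016,0.063,0.075,0.282,0.559,0.006
female,60-69,5,0.035,0.102,0.125,0.157,0.576,0.004
female,60-69,6,0.000,0.000,0.000,0.000,0.000,1.000
male,70+,1,0.211,0.327,0.283,0.007,0.075,0.097
male,70+,2,0.159,0.335,0.274,0.017,0.131,0.084
male,70+,3,0.168,0.335,0.277,0.012,0.109,0.099
male,70+,4,0.015,0.077,0.046,0.293,0.544,0.025
male,70+,5,0.037,0.134,0.090,0.121,0.598,0.020
male,70+,6,0.000,0.000,0.000,0.000,0.000,1.000
female,70+,1,0.290,0.334,0.252,0.006,0.049,0.068
female,70+,2,0.201,0.373,0.279,0.013,0.083,0.052
female,70+,3,0.202,0.373,0.279,0.013,0.081,0.052
female,70+,4,0.031,0.110,0.080,0.260,0.484,0.035
female,70+,5,0.065,0.183,0.134,0.127,0.471,0.019
female,70+,6,0.000,0.000,0.000,0.000,0.080,1.000
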