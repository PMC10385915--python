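sex,age_band,from_state,p1,p2,p3,p4,p5,p6
male,60-69,1,0.085,0.129,0.183,0.083,0.369,0.151
male,60-69,2,0.077,0.122,0.170,0.092,0.395,0.144
male,60-69,3,0.079,0.122,0.172,0.087,0.379,0.162
male,60-69,4,0.059,0.189,0.143,0.122,0.496,0.070
male,60-69,5,0.062,0.111,0.148,0.118,0.481,0.080
male,60-69,6,0.000,0.000,0.000,0.000,0.000,1.000
female,60-69,1,0.154,0.197,0.250,0.073,0.273,0.054
female,60-69,2,0.145,0.191,0.242,0.078,0.286,0.058
female,60-69,3,0.146,0.191,0.242,0.078,0.286,0.058
female,60-69,4,0.118,0.171,0.216,0.104,0.355,0.036
female,60-69,5,0.123,0.175,0.222,0.099,0.343,0.037
female,60-69,6,0.000,0.000,0.000,0.000,0.000,1.000
male,70+,1,0.093,0.193,0.156,0.040,0.184,0.334
male,70+,2,0.093,0.194,0.157,0.043,0.196,0.318
male,70+,3,0.092,0.191,0.154,0.041,0.189,0.333
male,70+,4,0.088,0.196,0.154,0.074,0.306,0.182
male,70+,5,0.091,0.200,0.158,0.068,0.287,0.196
male,70+,6,0.000,0.000,0.000,0.000,0.000,1.000
female,70+,1,0.155,0.262,0.196,0.029,0.116,0.242
female,70+,2,0.157,0.265,0.199,0.031,0.121,0.227
female,70+,3,0.157,0.266,0.199,0.031,0.121,0.227
female,70+,4,0.148,0.262,0.196,0.051,0.175,0.169
female,70+,5,0.154,0.269,0.201,0.046,0.163,0.168
female,70+,6,0.000,0.000,0.000,0.000,0.080,1.000
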