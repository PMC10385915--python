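sex,age_band,state,y2020,y2025,y2030,y2035
male,60-69,1,5.504,6.168,7.575,8.187
male,60-69,2,9.387,10.448,12.810,13.857
male,60-69,3,12.716,14.190,17.409,18.828
male,60-69,4,8.847,9.682,11.852,12.817
male,60-69,5,36.727,40.296,49.340,53.365
male,60-69,6,9.217,14.428,19.095,23.263
female,60-69,1,10.579,11.711,14.449,15.575
female,60-69,2,14.310,15.803,19.498,21.013
female,60-69,3,18.132,20.021,24.707,26.624
female,60-69,4,6.779,7.410,9.136,9.844
female,60-69,5,24.133,26.432,32.588,35.120
female,60-69,6,20.806,23.39,25.849,28.192
male,70+,1,5.541,7.351,8.725,10.645
male,70+,2,11.694,15.589,18.516,22.591
male,70+,3,9.389,12.495,14.836,18.100
male,70+,4,3.001,4.191,4.976,6.073
male,70+,5,13.269,18.285,21.792,26.598
male,70+,6,9.521,13.797,16.919,19.185
female,70+,1,10.291,14.007,16.785,20.390
female,70+,2,17.598,23.882,28.613,34.754
female,70+,3,13.172,17.877,21.419,26.017
female,70+,4,2.358,3.073,3.672,4.459
female,70+,5,8.857,11.665,13.948,16.940
female,70+,6,8.005,11.922,14.993,17.396
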