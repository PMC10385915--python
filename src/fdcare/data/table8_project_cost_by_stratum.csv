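sex,age_band,state,y2020,y2025,y2030,y2035
male,60-69,1,109.950,123.216,151.314,163.539
male,60-69,2,44.163,49.156,60.268,65.194
male,60-69,3,178.340,199.017,244.171,264.073
male,60-69,5,14.486,15.893,19.460,21.048
female,60-69,1,211.312,233.926,288.622,311.121
female,60-69,2,67.327,74.352,91.732,98.863
female,60-69,3,254.313,280.805,346.516,373.406
female,60-69,5,9.518,10.425,12.853,13.852
male,70+,1,110.687,146.831,174.288,212.632
male,70+,2,55.017,73.345,87.114,106.285
male,70+,3,131.680,175.240,208.073,253.858
male,70+,5,5.233,7.212,8.595,10.491
female,70+,1,205.571,279.794,335.293,407.300
female,70+,2,82.797,112.362,134.618,163.513
female,70+,3,184.737,250.736,300.410,364.899
female,70+,5,3.493,4.601,5.501,6.681
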