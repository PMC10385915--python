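sex,age_band,state,y2020,y2025,y2030,y2035
male,60-69,1,33.875,52.012,78.881,97.511
male,60-69,2,10.742,16.381,24.803,30.687
male,60-69,3,38.4,58.712,88.959,110.041
male,60-69,5,11.234,16.887,25.536,31.589
female,60-69,1,65.105,98.745,150.46,185.507
female,60-69,2,16.375,24.777,37.752,46.536
female,60-69,3,54.759,82.84,126.246,155.601
female,60-69,5,7.382,11.077,16.866,20.789
male,70+,1,34.102,61.98,90.857,126.782
male,70+,2,13.381,24.441,35.851,50.029
male,70+,3,28.353,51.697,75.807,105.785
male,70+,5,4.058,7.663,11.278,15.745
female,70+,1,63.336,118.106,242.854,242.854
female,70+,2,20.138,37.443,76.967,76.967
female,70+,3,39.778,73.969,152.056,152.056
female,70+,5,2.709,4.888,10.028,10.028
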