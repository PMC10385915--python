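sex,age_band,state,y2020,y2025,y2030,y2035
male,60-69,1,11.802,18.121,27.482,33.973
male,60-69,2,3.742,5.707,8.641,10.692
male,60-69,3,13.379,20.455,30.994,38.339
male,60-69,5,3.914,5.883,8.897,11.006
female,60-69,1,22.683,34.403,52.421,64.631
female,60-69,2,5.705,8.632,13.153,16.213
female,60-69,3,19.078,28.862,43.985,54.212
female,60-69,5,2.572,3.859,5.876,7.243
male,70+,1,11.881,21.594,31.655,44.172
male,70+,2,4.662,8.515,12.491,17.43
male,70+,3,9.878,18.012,26.411,36.856
male,70+,5,1.414,2.67,3.929,5.485
female,70+,1,22.066,41.149,84.611,84.611
female,70+,2,7.016,13.045,26.815,26.815
female,70+,3,13.859,25.771,52.977,52.977
female,70+,5,0.944,1.703,3.494,3.494
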