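category,item,y2020,y2025,y2030,y2035
Daily life care,Bathing assistance,16.318,19.884,24.111,27.666
Daily life care,Meal help,122.739,149.558,181.348,208.093
Daily life care,Housekeeping,81.898,100.231,121.438,139.751
Primary Care,Intramuscular injection,60.635,74.208,89.909,103.467
Primary Care,Dressing change (medicine),62.007,75.887,91.944,105.809
Primary Care,Intravenous infusion,38.199,46.750,56.641,65.183
Primary Care,Blood specimen collection,12.849,15.726,19.053,21.926
Primary Care,Assist in turning and tapping to expel sputum,123.116,150.675,182.556,210.085
Primary Care,Pressure ulcer prevention care,130.152,159.287,192.990,222.092
Professional Medical Care Services,Urinary catheterization,146.614,179.434,217.400,250.183
Professional Medical Care Services,Bladder Flushing,80.894,98.569,119.521,137.148
Professional Medical Care Services,Artificial anal stool bag care,63.547,77.433,93.891,107.738
Professional Medical Care Services,Stoma Care,143.707,175.107,212.327,243.641
Professional Medical Care Services,Enema,38.715,47.382,57.407,66.064
Professional Medical Care Services,Nasal feeding,140.354,171.022,207.373,237.957
Professional Medical Care Services,Oxygenation,82.717,101.233,122.652,141.148
Auxiliary monitoring,Blood pressure monitoring,2.224,2.721,3.297,3.794
Auxiliary monitoring,Blood glucose Monitoring,22.403,27.419,33.220,38.229
Spiritual comfort,Hospice care,51.556,62.821,76.173,87.407
Healthcare,Rehab Physical Therapy,130.010,159.113,192.779,221.850
Healthcare,Accompanying to medical appointments,15.048,18.171,22.043,25.196
Healthcare,Drug administration,75.126,90.716,110.044,125.787
Senior Education,Health consultation,3.938,4.755,5.769,6.594
Senior Education,Caregiver guidance,1.722,2.079,2.522,2.883
Senior Education,Legal advice,5.247,6.336,7.685,8.785
Senior Education,Security guidance,14.567,17.590,21.338,24.391
Senior Education,Psychological Counseling,2.321,2.802,3.399,3.886
Total,Above all projects,1668.623,2036.910,2468.829,2836.754
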