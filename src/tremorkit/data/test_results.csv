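patient_id,test_id,age,years_diagnosed,dominant_freq_x_hz,dominant_freq_y_hz,dominant_freq_z_hz,energy_band_hz,avg_amplitude_m_s2
1,1,65,5,4.3519,4.3519,4.3519,3.0-5.0,1.6112
1,2,65,5,4.4049,4.3599,4.4049,3.0-5.0,0.7929
1,3,65,5,5.8124,6.0827,7.2317,5.0-7.0,1.3023
1,4,65,5,1.8769,7.2573,1.9394,1.0-3.0,1.0741
1,5,65,5,0.8148,0.5926,0.8148,1.0-3.0,1.2816
1,6,65,5,0.8418,0.9620,0.8418,1.0-3.0,1.9874
2,1,75,8,3.7177,11.2935,3.7177,5.0-7.0,1.1944
2,2,75,8,7.7614,6.1275,3.7582,5.0-7.0,1.2913
2,3,75,8,6.5899,6.1728,8.2583,5.0-7.0,1.7209
2,4,75,8,5.6081,5.6081,5.8710,5.0-7.0,1.7848
2,5,75,8,0.6536,0.6536,2.3693,1.0-3.0,1.4575
2,6,75,8,NaN,NaN,NaN,NaN,NaN
3,1,60,4,4.3062,2.8506,9.9466,5.0-7.0,0.8045
3,2,60,4,7.9697,7.5828,8.8982,7.0-9.0,1.1463
3,3,60,4,7.0535,4.2176,7.0535,7.0-9.0,0.9343
3,4,60,4,NaN,NaN,NaN,NaN,NaN
3,5,60,4,NaN,NaN,NaN,NaN,NaN
3,6,60,4,0.6270,3.5114,7.3990,3.0-5.0,0.9048
4,1,73,7,3.9683,3.9683,4.0431,3.0-5.0,1.1422
4,2,73,7,4.2301,5.4992,1.9741,5.0-7.0,1.2175
4,3,73,7,4.1249,8.1976,4.1249,3.0-5.0,1.0849
4,4,73,7,5.6096,5.6096,4.1227,5.0-7.0,1.0899
4,5,73,7,NaN,NaN,NaN,NaN,NaN
4,6,73,7,0.7944,0.6355,1.4829,1.0-3.0,0.6899
5,1,68,10,9.8692,3.8257,5.5999,7.0-9.0,0.8235
5,2,68,10,1.6920,5.6402,6.3922,5.0-7.0,1.0413
5,3,68,10,5.6004,8.4379,4.6296,5.0-7.0,1.2352
5,4,68,10,2.9380,4.3403,1.9364,1.0-3.0,1.1354
5,5,68,10,1.9960,5.4336,2.0515,1.0-3.0,1.0606
5,6,68,10,0.6578,0.6072,9.4111,1.0-3.0,0.7640
6,1,68,9,4.4767,4.4579,4.4579,3.0-5.0,0.5721
6,2,68,9,1.6920,5.6402,6.3922,5.0-7.0,1.0413
6,3,68,9,5.7319,5.7319,5.7319,5.0-7.0,1.1137
6,4,68,9,NaN,NaN,NaN,NaN,NaN
6,5,68,9,NaN,NaN,NaN,NaN,NaN
6,6,68,9,0.7663,5.3640,0.6705,5.0-7.0,0.9140
7,1,77,12,3.6353,5.3132,7.2707,3.0-5.0,1.6510
7,2,77,12,3.8354,4.2422,3.7192,3.0-5.0,1.2830
7,3,77,12,5.1743,5.1743,4.4374,3.0-5.0,0.5210
7,4,77,12,4.8864,5.2132,4.9642,5.0-7.0,0.5980
7,5,77,12,NaN,NaN,NaN,NaN,NaN
7,6,77,12,4.2735,2.1368,4.2735,3.0-5.0,8.9833
8,1,62,2,4.3851,4.4657,4.4174,3.0-5.0,0.6785
8,2,62,2,5.2426,4.6135,5.2426,5.0-7.0,0.5549
8,3,62,2,5.0403,5.0563,5.0403,3.0-5.0,0.4965
8,4,62,2,5.2104,5.2104,5.2104,5.0-7.0,0.6632
8,5,62,2,NaN,NaN,NaN,NaN,NaN
8,6,62,2,NaN,NaN,NaN,NaN,NaN
9,1,66,6,5.3168,5.4796,5.5339,5.0-7.0,1.2753
9,2,66,6,6.3301,5.4364,5.4364,5.0-7.0,1.6584
9,3,66,6,5.6926,5.6926,5.7453,5.0-7.0,0.7262
9,4,66,6,6.0171,6.0171,6.0171,5.0-7.0,1.1919
9,5,66,6,2.6953,4.0704,5.7206,5.0-7.0,0.9993
9,6,66,6,1.1111,1.1111,1.0101,1.0-3.0,1.9980
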