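class,length_um,thickness_um,r1,r2
hermaphrodite,1091.857,54.212,0.447214,0.471405
hermaphrodite,1097.121,61.192,0.447214,0.500000
hermaphrodite,1129.743,62.529,0.392232,0.554700
hermaphrodite,1170.074,50.588,0.353553,0.500000
hermaphrodite,1014.370,51.814,0.333333,0.333333
hermaphrodite,921.801,59.768,0.342997,0.447214
hermaphrodite,1158.049,53.047,0.353553,0.471405
hermaphrodite,1160.166,52.951,0.316228,0.333333
hermaphrodite,1088.101,55.564,0.333333,0.471405
hermaphrodite,897.533,49.239,0.447214,0.500000
hermaphrodite,1060.675,51.385,0.392232,0.500000
hermaphrodite,1054.767,58.923,0.333333,0.447214
hermaphrodite,1161.711,59.863,0.277350,0.500000
hermaphrodite,982.754,55.244,0.333333,0.447214
hermaphrodite,1019.687,49.017,0.353553,0.500000
hermaphrodite,1143.144,58.987,0.333333,0.333333
hermaphrodite,1017.573,56.717,0.392232,0.392232
hermaphrodite,1022.267,55.671,0.333333,0.333333
hermaphrodite,1167.377,51.610,0.333333,0.333333
hermaphrodite,1133.738,51.688,0.333333,0.353553
hermaphrodite,1101.322,65.984,0.250000,0.250000
hermaphrodite,1128.464,60.092,0.277350,0.333333
hermaphrodite,1177.212,62.197,0.277350,0.500000
hermaphrodite,972.579,56.821,0.392232,0.447214
hermaphrodite,979.907,53.723,0.333333,0.447214
hermaphrodite,1155.330,55.659,0.392232,0.447214
hermaphrodite,962.380,53.648,0.277350,0.277350
hermaphrodite,1071.448,56.744,0.277350,0.316228
hermaphrodite,1001.880,56.973,0.316228,0.392232
hermaphrodite,1076.179,61.912,0.316228,0.342997
hermaphrodite,946.738,62.835,0.353553,0.554700
hermaphrodite,916.913,57.598,0.277350,0.392232
hermaphrodite,1146.837,54.855,0.277350,0.316228
hermaphrodite,1214.986,56.056,0.316228,0.333333
hermaphrodite,1013.315,56.205,0.333333,0.471405
hermaphrodite,989.021,47.632,0.333333,0.333333
hermaphrodite,959.206,50.125,0.333333,0.333333
hermaphrodite,1158.609,52.402,0.316228,0.500000
hermaphrodite,1139.124,63.758,0.485071,0.554700
hermaphrodite,1156.529,50.560,0.316228,0.353553
hermaphrodite,921.367,58.787,0.277350,0.392232
hermaphrodite,996.595,61.090,0.316228,0.392232
hermaphrodite,1062.877,54.260,0.392232,0.447214
hermaphrodite,1124.991,52.841,0.333333,0.471405
hermaphrodite,1169.164,54.314,0.316228,0.392232
hermaphrodite,934.896,60.241,0.333333,0.500000
male,786.562,47.860,0.500000,0.685994
male,790.548,47.725,0.333333,0.500000
male,862.048,37.150,0.500000,0.666667
male,839.016,39.077,0.500000,0.666667
male,877.866,46.780,0.353553,0.685994
male,860.353,39.974,0.353553,0.707107
male,841.458,44.738,0.500000,0.784465
male,883.563,38.589,0.447214,0.620174
male,857.479,41.290,0.500000,0.620174
male,815.658,48.639,0.353553,0.727607
male,793.370,37.650,0.353553,0.632456
male,755.536,47.924,0.353553,0.685994
male,776.631,43.195,0.333333,0.500000
male,836.890,42.962,0.353553,0.784465
male,714.658,44.458,0.333333,0.500000
male,842.138,43.146,0.353553,0.542326
male,875.767,49.112,0.500000,0.685994
male,900.877,41.646,0.447214,0.666667
male,759.240,45.631,0.353553,0.685994
male,723.765,38.411,0.447214,0.707107
male,769.840,39.460,0.632456,0.632456
male,737.664,48.111,0.333333,0.750000
male,731.302,36.860,0.353553,0.666667
male,739.861,44.200,0.353553,0.559017
male,840.354,38.311,0.500000,0.632456
male,899.993,47.086,0.333333,0.750000
male,718.327,37.761,0.554700,0.632456
male,841.443,41.926,0.353553,0.707107
male,862.048,44.159,0.333333,0.559017
male,797.932,42.148,0.353553,0.559017
male,803.035,36.724,0.447214,0.666667
male,838.836,41.402,0.353553,0.707107
male,760.147,46.077,0.500000,0.620174
male,703.254,43.136,0.500000,0.685994
male,704.017,36.908,0.632456,0.707107
male,758.493,46.957,0.353553,0.685994
male,750.083,44.949,0.353553,0.542326
male,867.985,46.826,0.353553,0.666667
male,802.973,37.937,0.333333,0.942809
male,706.862,43.394,0.500000,0.620174
male,831.092,43.720,0.447214,0.894427
male,865.359,39.401,0.447214,0.632456
male,765.723,47.562,0.353553,0.666667
male,748.231,39.922,0.353553,0.554700
male,778.382,36.693,0.447214,0.790569
male,797.135,37.897,0.353553,0.666667
larva,297.774,17.026,0.500000,0.500000
larva,588.164,20.904,0.500000,0.500000
larva,537.408,27.909,0.500000,0.632456
larva,347.322,14.962,0.500000,0.707107
larva,587.290,31.798,0.353553,0.632456
larva,595.377,26.753,0.500000,0.500000
larva,349.603,22.720,0.353553,0.353553
larva,578.518,21.033,0.500000,0.500000
larva,371.336,26.510,0.447214,0.447214
larva,405.822,21.967,0.447214,0.632456
larva,376.658,22.883,0.500000,0.500000
larva,316.219,17.102,0.500000,0.500000
larva,343.025,19.953,0.500000,0.500000
larva,400.719,26.886,0.333333,0.471405
larva,346.267,17.204,0.500000,0.500000
larva,380.164,27.784,0.353553,0.666667
larva,284.464,25.249,0.500000,0.500000
larva,550.658,26.471,0.447214,0.707107
larva,491.597,16.759,0.707107,1.000000
larva,310.070,25.072,0.500000,0.632456
larva,296.094,15.839,0.500000,0.500000
larva,457.993,30.166,0.333333,0.471405
larva,571.486,30.681,0.500000,0.500000
larva,554.945,26.190,0.447214,0.632456
larva,470.822,24.408,0.500000,0.500000
larva,312.884,23.091,0.333333,0.500000
larva,287.226,18.681,0.500000,0.500000
larva,290.775,20.778,0.353553,0.447214
larva,566.384,18.425,0.500000,0.500000
larva,307.009,16.101,0.500000,0.500000
larva,568.074,16.809,0.500000,1.000000
larva,296.153,19.402,0.447214,0.500000
larva,466.354,17.485,0.500000,0.707107
larva,337.135,26.192,0.500000,0.500000
larva,461.440,30.856,0.500000,0.500000
larva,284.242,16.202,0.500000,0.707107
larva,597.272,28.012,0.447214,0.500000
larva,537.710,23.572,0.447214,0.447214
larva,402.658,16.159,0.707107,0.707107
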