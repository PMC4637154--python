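# fmgap 0.1.0
# parameter_set_hash 2efe2bc864d395c6
# fixture gj_curves_coarse.csv
V_j,Cx43,Cx45,Cx43_Cx45
-100.0,0.411313879,0.417620258,0.31428268
-95.0,0.417181667,0.417653223,0.314776555
-90.0,0.426491828,0.417717466,0.315216163
-85.0,0.441035908,0.417842073,0.315611708
-80.0,0.463213356,0.418082893,0.315977221
-75.0,0.495813617,0.418546942,0.316335716
-70.0,0.541242465,0.419438666,0.316730672
-65.0,0.600051425,0.421146648,0.317251671
-60.0,0.669324333,0.424402635,0.318091556
-55.0,0.742401908,0.430560676,0.319673206
-50.0,0.811048041,0.442043597,0.322926344
-45.0,0.86884962,0.462912315,0.329869614
-40.0,0.913198989,0.499137539,0.344728149
-35.0,0.944853443,0.557292786,0.37560938
-30.0,0.966287413,0.639880305,0.435189008
-25.0,0.980267908,0.738795575,0.534660293
-20.0,0.98913169,0.835557616,0.666234964
-15.0,0.994594099,0.912743468,0.795416066
-10.0,0.997806755,0.963863798,0.890048165
-5.0,0.99948157,0.991447387,0.945606136
0.0,1.0,1.0,0.974140498
5.0,0.99948157,0.991447387,0.987837522
10.0,0.997806755,0.963863798,0.994231789
15.0,0.994594099,0.912743468,0.997201453
20.0,0.98913169,0.835557616,0.998593594
25.0,0.980267908,0.738795575,0.99926011
30.0,0.966287413,0.639880305,0.999589701
35.0,0.944853443,0.557292786,0.999759858
40.0,0.913198989,0.499137539,0.999852352
45.0,0.86884962,0.462912315,0.999905495
50.0,0.811048041,0.442043597,0.999937702
55.0,0.742401908,0.430560676,0.999958142
60.0,0.669324333,0.424402635,0.999971597
65.0,0.600051425,0.421146648,0.999980695
70.0,0.541242465,0.419438666,0.999986962
75.0,0.495813617,0.418546942,0.999991334
80.0,0.463213356,0.418082893,0.999994409
85.0,0.441035908,0.417842073,0.999996583
90.0,0.426491828,0.417717466,0.999998124
95.0,0.417181667,0.417653223,0.99999922
100.0,0.411313879,0.417620258,1.0
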