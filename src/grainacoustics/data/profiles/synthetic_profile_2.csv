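bin_hz,power
0,4.743626566e-05
172.265625,0.0002485904134
344.53125,0.0005016783407
516.796875,0.0005684567401
689.0625,0.0005884206903
861.328125,0.0005968848676
1033.59375,0.0005711783161
1205.859375,0.0005451307095
1378.125,0.0006377886481
1550.390625,0.0006771963359
1722.65625,0.000630618857
1894.921875,0.000839048074
2067.1875,0.001379176139
2239.453125,0.001590162982
2411.71875,0.002618952912
2583.984375,0.003723194304
2756.25,0.005559329997
2928.515625,0.009968924278
3100.78125,0.03043225189
3273.046875,0.03244729592
3445.3125,0.009009536177
3617.578125,0.02726574321
3789.84375,0.1471899771
3962.109375,0.2849326985
4134.375,0.215962226
4306.640625,0.06288719052
4478.90625,0.008130176118
4651.171875,0.02124670994
4823.4375,0.03807190353
4995.703125,0.01838290513
5167.96875,0.006845149564
5340.234375,0.004547473926
5512.5,0.002550356568
5684.765625,0.002403498318
5857.03125,0.001679925427
6029.296875,0.001280214573
6201.5625,0.0007770568524
6373.828125,0.0006478806328
6546.09375,0.0004868936947
6718.359375,0.0005434299501
6890.625,0.0005717274505
7062.890625,0.0005027356021
7235.15625,0.0005132430923
7407.421875,0.0005677526139
7579.6875,0.0005178571828
7751.953125,0.0005190295465
7924.21875,0.0005563184631
8096.484375,0.0005807496956
8268.75,0.000588249847
8441.015625,0.0004938627384
8613.28125,0.0004806647436
8785.546875,0.0004656251508
8957.8125,0.0005236921978
9130.078125,0.0006277038649
9302.34375,0.0005340246844
9474.609375,0.0004844901511
9646.875,0.0005680108485
9819.140625,0.0005632095071
9991.40625,0.0007759487637
10163.67188,0.0007577182602
10335.9375,0.0006776998975
10508.20312,0.0004763090577
10680.46875,0.0004345050359
10852.73438,0.0006037273732
11025,0.0006246441191
11197.26562,0.0005714303941
11369.53125,0.0005146144159
11541.79688,0.0004959283462
11714.0625,0.0006454089979
11886.32812,0.0007229241822
12058.59375,0.0006760666422
12230.85938,0.0006936566868
12403.125,0.0007623362937
12575.39062,0.0006850257602
12747.65625,0.0005773230697
12919.92188,0.0005059908498
13092.1875,0.0004262893739
13264.45312,0.0005669511969
13436.71875,0.0005595566755
13608.98438,0.0005131964638
13781.25,0.0005466860689
13953.51562,0.0004145207228
14125.78125,0.0004096890086
14298.04688,0.000426682134
14470.3125,0.0004078267849
14642.57812,0.0004925845559
14814.84375,0.0006151581947
14987.10938,0.0006636867016
15159.375,0.0006021027669
15331.64062,0.0005116428505
15503.90625,0.0004374307536
15676.17188,0.000514852562
15848.4375,0.0006201098402
16020.70312,0.0005800380969
16192.96875,0.0007360960508
16365.23438,0.0007319671958
16537.5,0.0004962341882
16709.76562,0.000446518666
16882.03125,0.000589797331
17054.29688,0.0006573829093
17226.5625,0.0005778248087
17398.82812,0.0004765261711
17571.09375,0.0006046521359
17743.35938,0.000609559779
17915.625,0.000529314856
18087.89062,0.0005374699371
18260.15625,0.0005629150269
18432.42188,0.000647251119
18604.6875,0.0005267125634
18776.95312,0.0005998728117
18949.21875,0.000671412847
19121.48438,0.0005299572547
19293.75,0.0006080119949
19466.01562,0.0005745076436
19638.28125,0.0006637395498
19810.54688,0.0006984722172
19982.8125,0.0005884042952
20155.07812,0.0006411840494
20327.34375,0.0008717355836
20499.60938,0.0006924777122
20671.875,0.0005233763342
20844.14062,0.0005395352717
21016.40625,0.0005352871727
21188.67188,0.0006366273819
21360.9375,0.000599278659
21533.20312,0.000510355276
21705.46875,0.0005730860432
21877.73438,0.0006762253151
22050,0.0003543571695
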