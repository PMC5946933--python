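bin_hz,power
0,3.882081705e-05
172.265625,0.0002525431545
344.53125,0.0004798994459
516.796875,0.0005338138635
689.0625,0.0005116327079
861.328125,0.0005234846754
1033.59375,0.0005840294415
1205.859375,0.0006355654478
1378.125,0.0005939202594
1550.390625,0.0006482363057
1722.65625,0.0008431836237
1894.921875,0.0008680636331
2067.1875,0.001305245067
2239.453125,0.001407283165
2411.71875,0.002517749721
2583.984375,0.003036153693
2756.25,0.006347329203
2928.515625,0.01074980044
3100.78125,0.03113286769
3273.046875,0.0328020453
3445.3125,0.009078527646
3617.578125,0.02703535872
3789.84375,0.1440360403
3962.109375,0.2832941465
4134.375,0.219525222
4306.640625,0.06629869293
4478.90625,0.008726418514
4651.171875,0.02148342526
4823.4375,0.0366032621
4995.703125,0.01757658895
5167.96875,0.007167604911
5340.234375,0.004816325784
5512.5,0.002634256984
5684.765625,0.001911091561
5857.03125,0.001255639064
6029.296875,0.00114770361
6201.5625,0.0007319557414
6373.828125,0.0008354030248
6546.09375,0.0007684592576
6718.359375,0.000659059938
6890.625,0.0005446407802
7062.890625,0.0005195483084
7235.15625,0.0004791346751
7407.421875,0.0004810868328
7579.6875,0.0005177484004
7751.953125,0.0005605743691
7924.21875,0.0005541375608
8096.484375,0.0005393312048
8268.75,0.0006384541166
8441.015625,0.0006032549818
8613.28125,0.0004999651284
8785.546875,0.0005647968498
8957.8125,0.0005887549306
9130.078125,0.0005620569875
9302.34375,0.0004960334262
9474.609375,0.0005401402301
9646.875,0.0006076713421
9819.140625,0.0005697978771
9991.40625,0.0005285897246
10163.67188,0.0004823177106
10335.9375,0.0005345480666
10508.20312,0.0005931206283
10680.46875,0.0005811506176
10852.73438,0.0005997324109
11025,0.0005918879987
11197.26562,0.0005908675387
11369.53125,0.0005356675573
11541.79688,0.000575360585
11714.0625,0.0005731160149
11886.32812,0.0005668285696
12058.59375,0.0005729229594
12230.85938,0.0005237144562
12403.125,0.0005234944604
12575.39062,0.000578541996
12747.65625,0.0005312696376
12919.92188,0.0005061151695
13092.1875,0.0005213066758
13264.45312,0.0005239260294
13436.71875,0.0004826553414
13608.98438,0.0005466438222
13781.25,0.0005596198204
13953.51562,0.0005249194172
14125.78125,0.0005059402427
14298.04688,0.000535156544
14470.3125,0.0005647013867
14642.57812,0.0005899166035
14814.84375,0.0006452295462
14987.10938,0.0005775899881
15159.375,0.0004476870279
15331.64062,0.0005515520188
15503.90625,0.0006235997574
15676.17188,0.000552996812
15848.4375,0.0005748811606
16020.70312,0.0005178084157
16192.96875,0.0005184719407
16365.23438,0.0005689280377
16537.5,0.0005337127086
16709.76562,0.0004975413721
16882.03125,0.0004633070036
17054.29688,0.0004868164724
17226.5625,0.000545765562
17398.82812,0.0005872459741
17571.09375,0.0006239982538
17743.35938,0.0005923154402
17915.625,0.0005008943614
18087.89062,0.000552153559
18260.15625,0.000555676666
18432.42188,0.0005687827496
18604.6875,0.000590481972
18776.95312,0.0006013601505
18949.21875,0.0005856144462
19121.48438,0.0006096048221
19293.75,0.0006145975677
19466.01562,0.0005066056627
19638.28125,0.0005354170552
19810.54688,0.0005590144367
19982.8125,0.0004710809369
20155.07812,0.0004708315594
20327.34375,0.0005641888272
20499.60938,0.0005465328962
20671.875,0.0005651937237
20844.14062,0.0005836217519
21016.40625,0.0005579178303
21188.67188,0.0005334709116
21360.9375,0.00048250376
21533.20312,0.0004789752135
21705.46875,0.0005304559683
21877.73438,0.0006051778181
22050,0.0003123873718
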