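0.0096694377916
0.342744325019
0.200495366048
-0.506183502845
0.713362269049
0.602650605927
0.23152338232
0.911095732353
0.921601862381
1.00167113537
0.978934292702
1.34142124004
0.79489561474
1.16705577417
1.08192420955
1.68487913197
1.45487729643
1.32471344194
1.10175464292
1.37140387969
1.49677996436
1.33314036478
2.08204814988
1.88881818331
-0.0325973735893
0.304004125187
1.07573661221
0.856969540943
1.07154467079
0.963265852554
1.79823504181
0.0645262989092
0.311197496437
1.40084912349
0.584035833813
0.476926799146
-0.221726357887
-0.892102332159
-0.0793902861294
-0.19400370426
-0.936659893016
-0.727069356543
-0.471038082549
-0.943317628956
-0.541843858024
-0.452258486265
-0.47491575557
-0.724087646583
-0.138142206793
0.060127451488
-0.16255971361
-0.657625861866
0.202703483652
-0.318784755965
0.4748571371
-0.390498595481
0.717917937277
0.369431592437
-0.124374445167
0.463586944272
0.766366803673
0.991000556625
0.473629109573
0.514378223149
1.26291492466
1.01513593973
1.44073667176
1.76521578689
0.61062255951
1.59813587568
2.10503235787
1.35123657781
1.08730158248
1.84706373102
1.56173950079
1.83339756104
1.15037601087
0.50760161131
1.10811727589
0.845150670226
1.35238508307
0.951421311231
-0.07610895193
0.0229551402037
0.941894518294
0.719345828454
-0.0594373472418
0.144870714674
0.258063604844
0.166137421192
0.274998439816
-0.12026793456
-0.370398035378
-0.514880058047
0.0928551575812
-1.59636895497
-0.562036536644
-0.483499948008
-1.20538335453
-0.304535010857
-0.760656748907
0.0457663725047
-0.385779907911
0.0860658722236
0.446299144345
0.123400044626
-0.402583743755
-0.611764202895
1.13737639447
0.323817223151
0.155717526183
0.692665224286
0.643609999046
1.28067601915
0.981687263262
1.07493953854
0.805832797724
1.48329479754
0.806050504716
1.71840074554
2.19698499918
0.708598798376
0.259594258422
1.80843937758
2.76665778184
0.97047939299
0.809668363284
1.67994049254
0.902623070865
0.995498006203
0.989063924899
1.33406578988
0.762071991347
0.993546307083
0.651049034841
0.19820112843
0.340086871128
-0.0957365128393
0.263941828647
-0.416538000825
-0.511170356691
0.660416160921
-0.189714768393
-0.275461760907
-0.0672156559348
-0.595884526928
-0.549283926424
-0.25836744976
-0.351500952976
-1.07964836347
-0.0760375757632
-0.766159289071
-0.963055717843
-0.835693560653
-0.518256538071
0.56513937914
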