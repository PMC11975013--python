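sample_id,class_label,analyte,delta13C
bacteria_01,bacteria,Ile,-17.1228
bacteria_01,bacteria,Leu,-20.7648
bacteria_01,bacteria,Lys,-11.9159
bacteria_01,bacteria,Phe,-21.6061
bacteria_01,bacteria,Thr,-7.8308
bacteria_01,bacteria,Val,-19.4448
bacteria_02,bacteria,Ile,-15.9503
bacteria_02,bacteria,Leu,-20.3565
bacteria_02,bacteria,Lys,-13.7034
bacteria_02,bacteria,Phe,-23.5084
bacteria_02,bacteria,Thr,-9.0635
bacteria_02,bacteria,Val,-18.7483
bacteria_03,bacteria,Ile,-16.2055
bacteria_03,bacteria,Leu,-20.3729
bacteria_03,bacteria,Lys,-13.5516
bacteria_03,bacteria,Phe,-23.3385
bacteria_03,bacteria,Thr,-11.1462
bacteria_03,bacteria,Val,-19.8827
bacteria_04,bacteria,Ile,-17.8119
bacteria_04,bacteria,Leu,-22.9625
bacteria_04,bacteria,Lys,-13.0684
bacteria_04,bacteria,Phe,-20.9017
bacteria_04,bacteria,Thr,-9.2711
bacteria_04,bacteria,Val,-17.1653
bacteria_05,bacteria,Ile,-15.9325
bacteria_05,bacteria,Leu,-20.7909
bacteria_05,bacteria,Lys,-13.6198
bacteria_05,bacteria,Phe,-21.6720
bacteria_05,bacteria,Thr,-10.4624
bacteria_05,bacteria,Val,-19.6616
bacteria_06,bacteria,Ile,-18.1300
bacteria_06,bacteria,Leu,-22.1088
bacteria_06,bacteria,Lys,-13.4209
bacteria_06,bacteria,Phe,-23.5141
bacteria_06,bacteria,Thr,-9.9269
bacteria_06,bacteria,Val,-17.0938
bacteria_07,bacteria,Ile,-18.0224
bacteria_07,bacteria,Leu,-21.9540
bacteria_07,bacteria,Lys,-14.5035
bacteria_07,bacteria,Phe,-21.0383
bacteria_07,bacteria,Thr,-8.8147
bacteria_07,bacteria,Val,-18.6234
bacteria_08,bacteria,Ile,-15.9392
bacteria_08,bacteria,Leu,-21.1012
bacteria_08,bacteria,Lys,-14.0965
bacteria_08,bacteria,Phe,-22.7499
bacteria_08,bacteria,Thr,-9.3267
bacteria_08,bacteria,Val,-19.6498
bacteria_09,bacteria,Ile,-18.2275
bacteria_09,bacteria,Leu,-21.2632
bacteria_09,bacteria,Lys,-12.8906
bacteria_09,bacteria,Phe,-20.9991
bacteria_09,bacteria,Thr,-7.3616
bacteria_09,bacteria,Val,-19.6039
bacteria_10,bacteria,Ile,-19.1261
bacteria_10,bacteria,Leu,-21.6239
bacteria_10,bacteria,Lys,-14.0492
bacteria_10,bacteria,Phe,-22.9462
bacteria_10,bacteria,Thr,-9.2189
bacteria_10,bacteria,Val,-17.6671
bacteria_11,bacteria,Ile,-16.5891
bacteria_11,bacteria,Leu,-20.6215
bacteria_11,bacteria,Lys,-11.7842
bacteria_11,bacteria,Phe,-23.0595
bacteria_11,bacteria,Thr,-9.0863
bacteria_11,bacteria,Val,-20.0358
bacteria_12,bacteria,Ile,-15.3926
bacteria_12,bacteria,Leu,-22.1243
bacteria_12,bacteria,Lys,-12.4055
bacteria_12,bacteria,Phe,-22.7679
bacteria_12,bacteria,Thr,-9.0124
bacteria_12,bacteria,Val,-19.2045
fungi_01,fungi,Ile,-22.0655
fungi_01,fungi,Leu,-26.2697
fungi_01,fungi,Lys,-20.1870
fungi_01,fungi,Phe,-26.1978
fungi_01,fungi,Thr,-14.6685
fungi_01,fungi,Val,-23.5905
fungi_02,fungi,Ile,-23.2055
fungi_02,fungi,Leu,-27.1929
fungi_02,fungi,Lys,-19.3170
fungi_02,fungi,Phe,-25.4595
fungi_02,fungi,Thr,-14.0302
fungi_02,fungi,Val,-23.5980
fungi_03,fungi,Ile,-22.3949
fungi_03,fungi,Leu,-25.4459
fungi_03,fungi,Lys,-19.7494
fungi_03,fungi,Phe,-26.3300
fungi_03,fungi,Thr,-14.2372
fungi_03,fungi,Val,-22.6226
fungi_04,fungi,Ile,-21.6097
fungi_04,fungi,Leu,-26.6146
fungi_04,fungi,Lys,-19.3441
fungi_04,fungi,Phe,-26.9855
fungi_04,fungi,Thr,-14.2497
fungi_04,fungi,Val,-24.3236
fungi_05,fungi,Ile,-23.2493
fungi_05,fungi,Leu,-25.8786
fungi_05,fungi,Lys,-19.5459
fungi_05,fungi,Phe,-26.9631
fungi_05,fungi,Thr,-14.9982
fungi_05,fungi,Val,-24.3880
fungi_06,fungi,Ile,-21.0521
fungi_06,fungi,Leu,-26.4420
fungi_06,fungi,Lys,-19.3998
fungi_06,fungi,Phe,-24.5963
fungi_06,fungi,Thr,-14.9022
fungi_06,fungi,Val,-24.4105
fungi_07,fungi,Ile,-23.9145
fungi_07,fungi,Leu,-25.6633
fungi_07,fungi,Lys,-20.3311
fungi_07,fungi,Phe,-26.7551
fungi_07,fungi,Thr,-14.6070
fungi_07,fungi,Val,-23.1904
fungi_08,fungi,Ile,-22.7329
fungi_08,fungi,Leu,-26.2972
fungi_08,fungi,Lys,-20.7206
fungi_08,fungi,Phe,-24.8776
fungi_08,fungi,Thr,-13.8591
fungi_08,fungi,Val,-24.9869
fungi_09,fungi,Ile,-23.7008
fungi_09,fungi,Leu,-28.2451
fungi_09,fungi,Lys,-21.1986
fungi_09,fungi,Phe,-27.8108
fungi_09,fungi,Thr,-15.5011
fungi_09,fungi,Val,-24.3464
plants_01,plants,Ile,-28.0317
plants_01,plants,Leu,-30.4856
plants_01,plants,Lys,-23.7255
plants_01,plants,Phe,-28.4580
plants_01,plants,Thr,-23.2350
plants_01,plants,Val,-27.8415
plants_02,plants,Ile,-28.1510
plants_02,plants,Leu,-31.1900
plants_02,plants,Lys,-24.8984
plants_02,plants,Phe,-28.5050
plants_02,plants,Thr,-21.7309
plants_02,plants,Val,-29.8233
plants_03,plants,Ile,-28.6346
plants_03,plants,Leu,-30.3444
plants_03,plants,Lys,-25.7880
plants_03,plants,Phe,-28.5434
plants_03,plants,Thr,-23.8504
plants_03,plants,Val,-27.8698
plants_04,plants,Ile,-27.2420
plants_04,plants,Leu,-29.3006
plants_04,plants,Lys,-23.7848
plants_04,plants,Phe,-29.4563
plants_04,plants,Thr,-23.7610
plants_04,plants,Val,-27.8384
plants_05,plants,Ile,-26.7955
plants_05,plants,Leu,-31.9578
plants_05,plants,Lys,-25.3342
plants_05,plants,Phe,-27.4072
plants_05,plants,Thr,-21.2716
plants_05,plants,Val,-28.4562
plants_06,plants,Ile,-28.5529
plants_06,plants,Leu,-31.7217
plants_06,plants,Lys,-24.8096
plants_06,plants,Phe,-29.4575
plants_06,plants,Thr,-21.4917
plants_06,plants,Val,-28.9393
plants_07,plants,Ile,-26.9673
plants_07,plants,Leu,-29.9066
plants_07,plants,Lys,-24.5802
plants_07,plants,Phe,-30.0092
plants_07,plants,Thr,-23.0951
plants_07,plants,Val,-28.7381
plants_08,plants,Ile,-26.9152
plants_08,plants,Leu,-31.6192
plants_08,plants,Lys,-23.9149
plants_08,plants,Phe,-29.1976
plants_08,plants,Thr,-22.0741
plants_08,plants,Val,-29.2530
plants_09,plants,Ile,-25.9969
plants_09,plants,Leu,-31.8785
plants_09,plants,Lys,-25.7386
plants_09,plants,Phe,-30.5570
plants_09,plants,Thr,-22.3737
plants_09,plants,Val,-28.5981
plants_10,plants,Ile,-26.8972
plants_10,plants,Leu,-30.5878
plants_10,plants,Lys,-24.8944
plants_10,plants,Phe,-28.3607
plants_10,plants,Thr,-22.7959
plants_10,plants,Val,-29.0403
plants_11,plants,Ile,-25.8775
plants_11,plants,Leu,-30.1537
plants_11,plants,Lys,-26.2293
plants_11,plants,Phe,-26.9416
plants_11,plants,Thr,-20.3373
plants_11,plants,Val,-29.5848
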