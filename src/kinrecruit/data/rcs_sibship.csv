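individual_i,individual_j,relation,posterior
R001,R002,full_sib,1.0
R003,R004,full_sib,1.0
R005,R006,half_sib,0.976
R007,R008,half_sib,0.996
R009,R010,half_sib,0.968
R011,R012,half_sib,0.961
R013,R014,half_sib,0.958
R015,R016,half_sib,0.984
R017,R018,half_sib,0.964
R019,R020,half_sib,0.977
R021,R022,half_sib,0.99
R023,R024,half_sib,0.995
R025,R026,half_sib,0.991
R027,R028,half_sib,0.966
R029,R030,half_sib,0.96
R031,R032,half_sib,0.98
R033,R034,half_sib,0.998
R035,R036,half_sib,0.974
R037,R038,half_sib,0.977
R039,R040,half_sib,0.994
R041,R042,half_sib,0.834
R042,R043,half_sib,0.766
R044,R045,half_sib,0.815
R045,R046,half_sib,0.843
R047,R048,half_sib,0.768
R048,R049,half_sib,0.939
R050,R051,half_sib,0.917
R051,R052,half_sib,0.843
R053,R054,half_sib,0.939
R054,R055,half_sib,0.774
R056,R057,half_sib,0.768
R057,R058,half_sib,0.857
R059,R060,half_sib,0.832
R060,R061,half_sib,0.852
R062,R063,half_sib,0.881
R063,R064,half_sib,0.863
R065,R066,half_sib,0.892
R066,R067,half_sib,0.889
R068,R069,half_sib,0.785
R069,R070,half_sib,0.858
R071,R072,half_sib,0.783
R072,R073,half_sib,0.809
R073,R074,half_sib,0.806
R071,R074,full_sib,1.0
R075,R076,half_sib,0.82
R076,R077,half_sib,0.924
R077,R078,half_sib,0.786
R078,R079,half_sib,0.894
R159,R164,half_sib,0.75
R091,R094,half_sib,0.308
R125,R139,half_sib,0.686
R096,R115,half_sib,0.368
R126,R155,half_sib,0.526
R125,R158,half_sib,0.329
R096,R166,half_sib,0.371
R128,R129,half_sib,0.31
R124,R145,half_sib,0.467
R107,R128,half_sib,0.308
R101,R123,half_sib,0.509
R132,R135,half_sib,0.337
R131,R161,half_sib,0.34
R115,R146,half_sib,0.304
R080,R122,half_sib,0.38
R126,R129,half_sib,0.366
R103,R120,half_sib,0.648
R107,R154,half_sib,0.637
R095,R157,half_sib,0.602
R085,R095,half_sib,0.546
R108,R144,half_sib,0.507
R087,R089,half_sib,0.496
R118,R122,half_sib,0.499
R094,R145,half_sib,0.505
R094,R102,half_sib,0.614
R088,R093,half_sib,0.471
R097,R163,half_sib,0.598
R091,R132,half_sib,0.595
R116,R119,half_sib,0.666
R136,R139,half_sib,0.33
R093,R158,half_sib,0.582
R112,R123,half_sib,0.48
R146,R168,half_sib,0.481
R127,R139,half_sib,0.452
R138,R146,half_sib,0.402
R084,R129,half_sib,0.602
R123,R137,half_sib,0.57
R088,R097,half_sib,0.607
R088,R166,half_sib,0.542
R089,R127,half_sib,0.458
R160,R162,half_sib,0.607
R100,R109,half_sib,0.718
R135,R141,half_sib,0.407
R086,R122,half_sib,0.637
R124,R168,half_sib,0.732
R081,R117,half_sib,0.303
R086,R134,half_sib,0.38
R091,R163,half_sib,0.61
R108,R118,half_sib,0.539
R097,R139,half_sib,0.557
R105,R128,half_sib,0.574
R091,R138,half_sib,0.714
R110,R113,half_sib,0.643
R081,R094,half_sib,0.352
R096,R108,half_sib,0.724
R089,R113,half_sib,0.61
R157,R167,half_sib,0.724
R132,R157,half_sib,0.555
R101,R147,half_sib,0.691
R151,R154,half_sib,0.699
R130,R146,half_sib,0.496
R112,R120,half_sib,0.472
R084,R120,half_sib,0.59
R125,R147,half_sib,0.689
R092,R134,half_sib,0.309
R141,R148,half_sib,0.545
R120,R138,half_sib,0.346
R109,R123,half_sib,0.341
R123,R141,half_sib,0.628
R112,R128,half_sib,0.582
R086,R118,half_sib,0.729
R140,R163,half_sib,0.306
R092,R122,half_sib,0.469
R083,R085,half_sib,0.591
R086,R145,half_sib,0.325
R084,R114,half_sib,0.494
R087,R159,half_sib,0.477
R161,R166,half_sib,0.316
R102,R108,half_sib,0.668
R131,R139,half_sib,0.359
R140,R162,half_sib,0.654
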