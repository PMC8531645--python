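time_s,force_N
0.0,0.0101
0.0005,0.0149
0.001,0.022
0.0015,0.0319
0.002,0.046
0.0025,0.0656
0.003,0.0927
0.0035,0.1295
0.004,0.1793
0.0045,0.2457
0.005,0.3333
0.0055,0.4476
0.006,0.5952
0.0065,0.7836
0.007,1.0214
0.0075,1.3181
0.008,1.684
0.0085,2.1302
0.009,2.6676
0.0095,3.3075
0.01,4.0601
0.0105,4.9342
0.011,5.937
0.0115,7.0724
0.012,8.3411
0.0125,9.7396
0.013,11.2593
0.0135,12.8867
0.014,14.6026
0.0145,16.3822
0.015,18.1959
0.0155,20.0093
0.016,21.7845
0.0165,23.4811
0.017,25.0581
0.0175,26.4749
0.018,27.6935
0.0185,28.6799
0.019,29.406
0.0195,29.8504
0.02,30.0
0.0205,29.8504
0.021,29.406
0.0215,28.6799
0.022,27.6935
0.0225,26.4749
0.023,25.0581
0.0235,23.4811
0.024,21.7845
0.0245,20.0093
0.025,18.1959
0.0255,16.3822
0.026,14.6026
0.0265,12.8867
0.027,11.2593
0.0275,9.7396
0.028,8.3411
0.0285,7.0724
0.029,5.937
0.0295,4.9342
0.03,4.0601
0.0305,3.3075
0.031,2.6676
0.0315,2.1302
0.032,1.684
0.0325,1.3181
0.033,1.0214
0.0335,0.7836
0.034,0.5952
0.0345,0.4476
0.035,0.3333
0.0355,0.2457
0.036,0.1793
0.0365,0.1295
0.037,0.0927
0.0375,0.0656
0.038,0.046
0.0385,0.0319
0.039,0.022
0.0395,0.0149
0.04,0.0101
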