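time_s,force_N
0.0,0.0246
0.0005,0.0346
0.001,0.0484
0.0015,0.0671
0.002,0.0922
0.0025,0.1257
0.003,0.17
0.0035,0.228
0.004,0.3032
0.0045,0.3999
0.005,0.5232
0.0055,0.6787
0.006,0.8733
0.0065,1.1144
0.007,1.4104
0.0075,1.7703
0.008,2.2037
0.0085,2.7207
0.009,3.3313
0.0095,4.0454
0.01,4.8721
0.0105,5.8194
0.011,6.8938
0.0115,8.0993
0.012,9.4374
0.0125,10.9059
0.013,12.4992
0.0135,14.2075
0.014,16.0162
0.0145,17.9066
0.015,19.8554
0.0155,21.8351
0.016,23.8145
0.0165,25.7596
0.017,27.6343
0.0175,29.4013
0.018,31.0239
0.0185,32.4666
0.019,33.6968
0.0195,34.6857
0.02,35.4098
0.0205,35.8515
0.021,36.0
0.0215,35.8515
0.022,35.4098
0.0225,34.6857
0.023,33.6968
0.0235,32.4666
0.024,31.0239
0.0245,29.4013
0.025,27.6343
0.0255,25.7596
0.026,23.8145
0.0265,21.8351
0.027,19.8554
0.0275,17.9066
0.028,16.0162
0.0285,14.2075
0.029,12.4992
0.0295,10.9059
0.03,9.4374
0.0305,8.0993
0.031,6.8938
0.0315,5.8194
0.032,4.8721
0.0325,4.0454
0.033,3.3313
0.0335,2.7207
0.034,2.2037
0.0345,1.7703
0.035,1.4104
0.0355,1.1144
0.036,0.8733
0.0365,0.6787
0.037,0.5232
0.0375,0.3999
0.038,0.3032
0.0385,0.228
0.039,0.17
0.0395,0.1257
0.04,0.0922
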