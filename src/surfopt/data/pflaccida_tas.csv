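temperature_C,time_min,ethanol_pct,tas_mean,tas_sd,n
30,30,0,3.270,0.026,3
30,45,0,3.470,0.022,3
30,60,0,2.148,0.013,3
30,30,50,3.460,0.029,3
30,45,50,3.647,0.024,3
30,60,50,2.337,0.036,3
30,30,100,3.273,0.022,3
30,45,100,3.551,0.034,3
30,60,100,2.271,0.021,3
45,30,0,3.528,0.018,3
45,45,0,3.746,0.028,3
45,60,0,2.670,0.021,3
45,30,50,3.739,0.028,3
45,45,50,3.945,0.022,3
45,60,50,2.721,0.014,3
45,30,100,3.565,0.036,3
45,45,100,3.834,0.032,3
45,60,100,2.543,0.017,3
60,30,0,2.938,0.028,3
60,45,0,3.267,0.030,3
60,60,0,2.170,0.023,3
60,30,50,3.170,0.028,3
60,45,50,3.438,0.031,3
60,60,50,2.338,0.023,3
60,30,100,3.105,0.019,3
60,45,100,3.272,0.022,3
60,60,100,2.336,0.018,3
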