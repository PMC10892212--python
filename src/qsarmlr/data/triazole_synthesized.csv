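compound_id,split,AATSC8s,VE3_Dzs,nHsOH,CIC1,RotBFrac,pIC50
1,test,-0.006,-3.819,1,1.439,0.133,5.582
2,test,-0.010,-6.599,2,1.316,0.125,5.264
3,train,0.037,-7.797,2,1.316,0.125,5.264
4,train,-0.010,-8.587,2,1.316,0.125,5.270
5,train,-0.075,-5.287,3,1.328,0.118,5.241
6,train,0.064,-7.498,0,1.578,0.222,5.369
7,test,0.043,-6.004,0,1.578,0.222,5.367
8,test,0.184,-4.740,0,1.830,0.250,5.263
9,train,0.131,-5.434,0,1.633,0.263,5.271
10,train,0.122,-7.007,0,1.633,0.263,5.262
11,train,-0.174,-3.355,0,1.621,0.125,5.369
12,test,-0.169,-1.724,0,1.968,0.167,5.196
13,train,-0.128,-2.264,0,1.507,0.133,5.368
14,train,-0.128,-2.531,0,1.346,0.125,5.604
15,train,-0.127,-7.233,0,1.376,0.177,5.270
16,train,0.044,-4.375,0,1.376,0.177,5.607
17,train,-0.074,-2.618,1,2.214,0.182,5.198
18,test,0.032,-7.781,1,1.193,0.176,5.276
19,train,0.256,-4.965,1,1.396,0.211,5.485
20,train,0.220,-5.270,0,1.349,0.211,5.599
21,train,-0.004,-2.950,1,1.103,0.125,5.625
22,train,-0.021,-6.069,1,0.937,0.167,5.599
23,train,-0.103,-3.622,0,1.161,0.176,5.461
24,train,0.012,-5.284,0,1.161,0.176,5.633
25,train,-0.010,-6.839,0,1.161,0.176,5.644
26,train,-0.127,-9.690,0,1.055,0.167,5.359
27,train,-0.030,-6.929,1,1.011,0.167,5.636
28,train,-0.080,-4.901,0,1.069,0.133,5.613
29,train,0.001,-3.755,0,2.216,0.217,5.264
30,train,-0.037,-3.692,0,2.094,0.240,5.184
31,train,0.000,-4.566,0,2.641,0.083,5.267
32,train,0.026,-4.196,0,2.720,0.074,5.201
33,train,-0.019,-7.010,0,1.664,0.111,5.680
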