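compound_id,AATSC8s,VE3_Dzs,nHsOH,CIC1,RotBFrac,published_pIC50,published_leverage
P3,-0.106,-3.082,0,1.143,0.050,5.780,0.084
P4,-0.005,-3.524,0,1.103,0.118,5.738,0.023
P6,-0.084,-3.328,0,0.891,0.125,5.741,0.059
P7,0.083,-4.032,0,1.036,0.150,5.758,0.055
P10,0.077,-5.263,0,0.800,0.125,5.852,0.082
P14,0.113,-8.222,0,1.224,0.100,5.717,0.358
P19,0.109,-3.410,0,1.318,0.125,5.741,0.081
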