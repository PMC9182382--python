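compound_id,group,log_km,log_KAM,log_P,HBD,HBA,NRB,MW,TPSA,Vd,fu_plasma,fu_brain,log_BB,log_Kp,log_Ksc,log_Kwcell,log_PwHSA,log_KHSA,log_Pwpc,LD50
1,I,2.00,1.76,2.285,1,2,2,238.50,29.10,2.1,0.0750,0.06,-0.218,-5.095,1.713,-4.988,0.280,4.58,2.513,2600
2,I,2.46,2.13,2.937,1,2,2,252.52,29.10,2.3,0.0830,0.04,-0.026,-4.747,1.996,-4.833,0.554,4.60,3.106,2000
3,I,2.10,1.80,2.309,1,2,2,256.49,29.10,2.1,0.1000,0.06,-0.275,-5.075,1.717,-5.164,0.253,4.86,2.504,1800
4,I,2.72,2.31,2.971,1,2,2,272.94,29.10,2.4,0.0370,0.02,-0.098,-4.710,2.100,-5.071,0.694,4.70,3.254,1900
5,I,2.40,1.98,2.810,1,2,2,272.94,29.10,2.1,0.0510,0.03,-0.110,-4.836,1.989,-4.951,0.576,5.11,3.077,2000
6,I,3.20,2.60,3.755,1,2,2,307.39,29.10,2.8,0.0140,0.01,0.056,-4.244,2.529,-4.944,1.132,4.97,4.092,1800
7,I,2.96,2.39,3.488,1,2,2,307.39,29.10,2.4,0.0320,0.01,-0.011,-4.434,2.390,-5.020,0.993,5.53,3.847,2300
8,I,2.92,2.46,2.980,1,2,2,317.39,29.10,2.4,0.0540,0.02,-0.094,-4.818,2.134,-5.197,0.804,4.93,3.331,1400
9,I,0.40,-0.48,1.345,0,3,3,232.49,29.54,1.5,0.3100,0.30,-0.225,-5.538,1.097,-3.947,-0.492,4.17,1.522,1600
10,II,2.00,1.76,2.917,0,3,4,235.06,35.53,1.9,0.0920,0.07,0.263,-4.431,1.923,-3.279,0.313,4.36,3.132,550
11,II,2.95,2.39,4.067,0,3,4,283.53,35.53,2.1,0.0610,0.02,0.513,-3.731,2.541,-3.081,0.904,4.94,4.400,580
12,II,3.90,3.40,4.936,1,3,5,398.59,38.33,3.8,0.0030,0.01,0.227,-3.741,3.107,-5.275,1.642,5.35,5.420,780
13,II,4.30,4.00,5.386,1,3,5,412.62,38.33,4.0,0.0029,0.01,0.345,-3.504,3.308,-5.213,1.823,5.39,5.858,720
14,II,1.60,1.23,2.600,1,5,5,347.24,50.80,1.6,0.2400,0.12,-0.229,-5.761,1.608,-5.822,0.200,3.98,2.765,840
15,II,2.71,2.28,3.807,0,4,3,292.76,44.12,2.1,0.0690,0.02,0.448,-4.540,2.386,-3.999,1.017,4.17,4.240,750
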