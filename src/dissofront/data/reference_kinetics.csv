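formulation_id,model_id,r_squared,aic,msc,K,n,F0,k1,k2,m,selected
IBU,KP_F0,0.9883,-30.5054,4.0201,0.1326,0.8168,0.0000,,,,0
IBU,PS,0.9926,-35.5699,4.4805,,,,-0.2924,0.3694,0.3023,1
IP,KP_F0,0.9137,54.3542,1.8752,7.5186,0.4476,0.0000,,,,0
IP,PS,0.9841,35.4159,3.5978,,,,5.1761,-0.2349,0.8300,1
IP5E,KP_F0,0.8517,62.8388,1.2833,10.8410,0.3659,0.0000,,,,0
IP5E,PS,0.9593,48.5215,2.5848,,,,8.5832,-0.5887,0.7207,1
IP10E,KP_F0,0.8072,64.8453,0.8465,16.0896,0.2479,0.0000,,,,0
IP10E,PS,0.9472,50.4698,2.1534,,,,15.3681,-1.7729,0.5647,1
IP20E,KP_F0,0.8979,55.0850,0.8593,23.6146,0.1225,0.0000,,,,0
IP20E,PS,0.9385,49.5094,1.3662,,,,29.2022,-6.4220,0.3129,1
IP25E,KP_F0,0.8609,61.5988,0.7086,25.5091,0.1369,0.0000,,,,0
IP25E,PS,0.9299,53.6240,1.4336,,,,30.1941,-6.0546,0.3633,1
IP30E,KP_F0,0.9956,20.4575,3.8429,26.2569,0.1183,0.0000,,,,0
IP30E,PS,0.9973,16.1655,4.2330,,,,31.4441,-5.3375,0.1751,1
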