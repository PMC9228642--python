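formulation_id,medium,kind,mean_rate,sd_rate,n
IBU,water,wetting,0.201,0.025,5
IBU,HCl_pH1.2,wetting,0.000,0.000,5
IBU,water,gel,0.000,0.000,5
IBU,HCl_pH1.2,gel,0.000,0.000,5
IBU,water,erosion,0.000,0.000,5
IBU,HCl_pH1.2,erosion,0.000,0.000,5
IP,water,wetting,0.515,0.017,5
IP,HCl_pH1.2,wetting,0.084,0.005,5
IP,water,gel,0.184,0.008,5
IP,HCl_pH1.2,gel,0.171,0.004,5
IP,water,erosion,0.000,0.000,5
IP,HCl_pH1.2,erosion,0.000,0.000,5
IP5E,water,wetting,0.682,0.122,5
IP5E,HCl_pH1.2,wetting,0.159,0.083,5
IP5E,water,gel,0.053,0.004,5
IP5E,HCl_pH1.2,gel,0.049,0.004,5
IP5E,water,erosion,0.072,0.011,5
IP5E,HCl_pH1.2,erosion,0.058,0.009,5
IP10E,water,wetting,0.823,0.164,5
IP10E,HCl_pH1.2,wetting,0.236,0.091,5
IP10E,water,gel,0.035,0.002,5
IP10E,HCl_pH1.2,gel,0.025,0.007,5
IP10E,water,erosion,0.153,0.063,5
IP10E,HCl_pH1.2,erosion,0.118,0.044,5
IP20E,water,wetting,1.407,0.201,5
IP20E,HCl_pH1.2,wetting,0.388,0.143,5
IP20E,water,gel,,,5
IP20E,HCl_pH1.2,gel,,,5
IP20E,water,erosion,0.216,0.070,5
IP20E,HCl_pH1.2,erosion,0.194,0.068,5
IP25E,water,wetting,1.420,0.332,5
IP25E,HCl_pH1.2,wetting,0.485,0.148,5
IP25E,water,gel,,,5
IP25E,HCl_pH1.2,gel,,,5
IP25E,water,erosion,0.242,0.069,5
IP25E,HCl_pH1.2,erosion,0.283,0.055,5
IP30E,water,wetting,1.459,0.311,5
IP30E,HCl_pH1.2,wetting,0.516,0.187,5
IP30E,water,gel,,,5
IP30E,HCl_pH1.2,gel,,,5
IP30E,water,erosion,0.301,0.084,5
IP30E,HCl_pH1.2,erosion,0.375,0.092,5
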