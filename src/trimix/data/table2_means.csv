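region,color,n,european_mean,european_se,african_mean,african_se,amerindian_mean,amerindian_se
Para,White,66,0.782,0.026,0.077,0.011,0.141,0.022
Para,Brown,65,0.686,0.034,0.106,0.016,0.209,0.030
Para,Black,72,0.524,0.031,0.275,0.023,0.201,0.026
Bahia,White,48,0.668,0.037,0.244,0.033,0.088,0.012
Bahia,Brown,26,0.603,0.060,0.308,0.057,0.089,0.020
Bahia,Black,73,0.539,0.034,0.359,0.014,0.101,0.031
Ceara,White,31,0.758,0.032,0.133,0.017,0.109,0.021
Ceara,Brown,51,0.728,0.029,0.144,0.021,0.128,0.015
Rio de Janeiro,White,88,0.861,0.016,0.074,0.011,0.065,0.007
Rio de Janeiro,Brown,88,0.675,0.028,0.238,0.025,0.087,0.012
Rio de Janeiro,Black,88,0.427,0.032,0.495,0.032,0.079,0.009
Rio Grande do Sul,White,82,0.855,0.021,0.053,0.019,0.093,0.006
Rio Grande do Sul,Brown,78,0.442,0.037,0.444,0.035,0.114,0.016
Rio Grande do Sul,Black,29,0.431,0.062,0.459,0.052,0.110,0.026
Santa Catarina,Black,49,0.293,0.031,0.596,0.030,0.111,0.012
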