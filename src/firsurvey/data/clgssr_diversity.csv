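locus,size_min_bp,size_max_bp,na,ne,ho,he,pic,shannon_i
CLgSSR1,139,175,5,2.690,0.065,0.630,0.547,1.093
CLgSSR3,138,174,6,2.524,0.169,0.605,0.533,1.076
CLgSSR4,129,171,7,2.287,0.388,0.564,0.558,1.158
CLgSSR5,131,167,4,1.881,0.000,0.469,0.353,0.704
CLgSSR6,128,170,7,3.301,0.352,0.699,0.647,1.360
CLgSSR7,138,174,4,2.562,0.000,0.611,0.550,1.034
CLgSSR8,128,176,6,2.938,0.065,0.661,0.604,1.240
CLgSSR10,169,211,12,2.683,0.333,0.629,0.593,1.427
CLgSSR11,139,175,10,1.991,0.191,0.499,0.464,1.138
CLgSSR13,137,173,7,3.057,0.468,0.674,0.610,1.344
CLgSSR14,130,166,7,3.353,0.250,0.703,0.658,1.412
CLgSSR15,140,176,6,3.031,0.218,0.672,0.616,1.250
CLgSSR16,141,171,4,1.606,0.051,0.378,0.342,0.657
CLgSSR17,145,187,17,6.658,0.880,0.852,0.833,2.150
CLgSSR19,138,174,6,1.382,0.088,0.277,0.251,0.573
CLgSSR20,124,178,6,1.834,0.313,0.456,0.438,0.955
CLgSSR21,127,169,6,2.802,0.348,0.645,0.604,1.238
CLgSSR22,133,169,7,3.756,0.430,0.736,0.684,1.489
CLgSSR28,172,208,2,1.726,0.370,0.422,0.358,0.612
CLgSSR29,126,174,4,1.275,0.139,0.216,0.223,0.467
CLgSSR30,137,185,9,3.214,0.439,0.691,0.654,1.509
CLgSSR33,142,178,3,2.297,0.259,0.566,0.464,0.923
CLgSSR35,130,166,4,1.411,0.083,0.292,0.304,0.538
CLgSSR39,132,168,5,3.043,0.000,0.673,0.637,1.268
CLgSSR40,143,179,6,2.206,0.148,0.548,0.492,1.024
CLgSSR41,136,178,8,2.400,0.493,0.585,0.566,1.203
CLgSSR43,128,164,5,1.683,0.074,0.407,0.403,0.755
CLgSSR45,132,168,3,1.944,0.000,0.487,0.391,0.766
CLgSSR46,127,169,6,3.175,0.140,0.687,0.624,1.309
CLgSSR48,119,155,7,3.068,0.149,0.676,0.629,1.331
CLgSSR51,180,216,7,1.603,0.098,0.377,0.305,0.766
CLgSSR52,110,152,8,2.623,0.412,0.620,0.563,1.206
CLgSSR55,144,180,3,1.245,0.028,0.197,0.189,0.412
CLgSSR56,149,185,6,1.974,0.005,0.495,0.445,0.928
CLgSSR57,124,166,6,2.228,0.461,0.553,0.533,1.163
CLgSSR58,149,185,13,5.624,0.678,0.824,0.802,1.903
CLgSSR59,134,170,5,2.106,0.370,0.526,0.504,1.048
CLgSSR60,145,181,8,3.068,0.347,0.676,0.604,1.268
CLgSSR64,136,172,3,1.896,0.116,0.474,0.384,0.735
CLgSSR65,139,175,7,2.598,0.257,0.617,0.531,1.128
CLgSSR66,155,197,4,1.196,0.056,0.165,0.179,0.358
CLgSSR67,116,158,7,3.122,0.389,0.681,0.632,1.343
CLgSSR68,145,181,15,6.440,0.421,0.847,0.823,2.122
CLgSSR71,135,171,6,3.136,0.278,0.683,0.638,1.327
CLgSSR76,130,170,7,4.923,0.750,0.850,0.770,1.750
CLgSSR78,135,167,4,3.460,0.125,0.758,0.658,1.305
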