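genotype,GLA_S1,GLA_S2,LAI_S1,LAI_S2,RWC_S1,RWC_S2,CT_S1,CT_S2,Fi_S1,class_S1,Fi_S2,class_S2,Fi_combined,class_combined
DHL12,0.785,0.865,0.709,0.786,0.726,0.738,0.820,0.836,0.760,T,0.806,HT,0.783,T
DHL02,0.792,0.821,0.779,0.844,0.820,0.792,0.851,0.857,0.811,HT,0.829,HT,0.820,HT
DHL25,0.710,0.782,0.642,0.712,0.657,0.668,0.742,0.756,0.688,T,0.730,T,0.709,T
DHL30,0.876,0.907,0.862,0.933,0.907,0.876,0.988,0.900,0.908,HT,0.904,HT,0.906,HT
DHL07,0.688,0.758,0.621,0.689,0.636,0.647,0.754,0.696,0.675,T,0.697,T,0.686,T
DHL26,0.834,0.864,0.820,0.889,0.863,0.834,0.941,0.857,0.865,HT,0.861,HT,0.863,HT
Gemmeiza-9,0.850,0.847,0.729,0.809,0.710,0.797,0.885,0.817,0.793,T,0.818,HT,0.805,HT
DHL11,0.494,0.532,0.525,0.476,0.528,0.589,0.532,0.471,0.520,I,0.517,I,0.518,I
KSU106,0.400,0.406,0.311,0.360,0.392,0.487,0.380,0.372,0.371,S,0.406,I,0.389,S
Gemmeiza-12,0.473,0.479,0.379,0.399,0.462,0.567,0.454,0.409,0.442,I,0.464,I,0.453,I
DHL01,0.708,0.706,0.640,0.672,0.591,0.664,0.738,0.681,0.669,T,0.681,T,0.675,T
DHL14,0.330,0.352,0.274,0.198,0.340,0.343,0.320,0.196,0.316,S,0.272,S,0.294,S
DHL29,0.428,0.479,0.361,0.380,0.440,0.540,0.433,0.390,0.415,I,0.447,I,0.431,I
DHL15,0.347,0.408,0.303,0.310,0.376,0.379,0.330,0.275,0.339,S,0.343,S,0.341,S
DHL06,0.330,0.389,0.274,0.310,0.358,0.361,0.315,0.199,0.319,S,0.315,S,0.317,S
Misr1,0.892,0.925,0.878,0.951,0.878,0.937,0.980,0.917,0.907,HT,0.932,HT,0.920,HT
DHL05,0.822,0.906,0.743,0.824,0.761,0.773,0.852,0.832,0.794,T,0.834,HT,0.814,HT
Giza-168,0.695,0.766,0.628,0.697,0.643,0.654,0.726,0.741,0.673,T,0.714,T,0.694,T
DHL23,0.571,0.611,0.573,0.580,0.636,0.641,0.584,0.573,0.591,I,0.601,T,0.596,I
Sakha-93,0.372,0.396,0.294,0.332,0.404,0.368,0.321,0.295,0.347,S,0.348,S,0.348,S
DHL21,0.323,0.344,0.195,0.288,0.351,0.320,0.279,0.256,0.287,S,0.302,S,0.295,S
DHL22,0.347,0.370,0.289,0.295,0.377,0.344,0.300,0.276,0.328,S,0.321,S,0.325,S
DHL03,0.800,0.841,0.761,0.723,0.740,0.752,0.815,0.852,0.779,T,0.792,T,0.786,T
Pavone-76,0.776,0.804,0.803,0.787,0.803,0.776,0.833,0.839,0.804,HT,0.801,HT,0.803,HT
DHL08,0.834,0.864,0.864,0.846,0.863,0.834,0.896,0.903,0.864,HT,0.862,HT,0.863,HT
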