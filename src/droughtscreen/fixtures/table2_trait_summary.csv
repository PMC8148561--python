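trait,mean_full_s1,mean_limited_s1,mean_full_s2,mean_limited_s2,mean_combined
LWC,74.48,70.66,76.44,72.64,73.55
RWC,84.18,78.83,84.82,76.21,81.01
CT,17.38,19.73,17.02,19.91,18.51
LEWT,0.025,0.024,0.024,0.018,0.022
Pn,11.39,11.17,10.67,10.49,10.93
Gs,0.19,0.14,0.18,0.13,0.16
Ci,330.98,287.9,314.03,275.1,302.0
E,3.27,2.62,3.07,2.45,2.85
WUE,3.57,4.33,3.41,3.94,3.81
WUEi,61.92,83.8,61.04,70.10,69.21
Ls,0.26,0.34,0.30,0.38,0.32
GLN,38.53,29.78,36.57,36.20,35.27
FLA,23.54,20.14,23.03,20.35,21.76
GLA,88.14,58.52,91.08,71.22,77.24
LAI,3.80,2.12,3.45,2.30,2.96
DSW,8.44,7.62,8.23,7.58,7.97
DLW,1.01,0.90,0.99,0.90,0.95
TDW,9.46,8.52,9.21,8.48,8.92
DH,75.40,74.04,75.71,74.39,74.88
MD,121.61,117.28,121.84,117.63,119.59
GFD,45.95,43.00,46.13,43.35,44.61
NSP,579.07,440.39,462.93,379.80,465.55
PH,83.45,75.56,80.67,77.31,79.25
SL,10.06,9.38,8.63,8.10,9.04
NSS,16.01,15.25,14.66,13.59,14.88
NG,38.53,29.78,36.57,36.20,35.27
HW,51.72,44.88,44.01,41.51,45.53
GY,5.15,3.99,5.31,4.25,4.68
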