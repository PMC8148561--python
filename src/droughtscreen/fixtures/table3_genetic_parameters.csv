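trait,h2,gcv,pcv,ga,gg
LWC,36.06,2.76,4.60,2.51,3.14
RWC,86.36,10.73,11.55,16.64,20.55
CT,88.39,10.33,10.99,3.70,20.01
LEWT,88.30,26.71,28.42,0.01,51.71
Pn,80.81,11.73,13.05,2.37,21.73
Gs,30.37,8.53,15.48,0.02,9.69
Ci,38.81,3.82,6.13,14.79,4.90
E,38.92,7.48,11.99,0.27,9.61
WUE,55.30,9.52,12.80,0.56,14.58
WUEi,29.99,7.54,13.78,5.89,8.51
Ls,41.37,9.80,15.24,0.04,12.99
GLN,66.92,7.40,9.05,0.48,12.47
FLA,88.65,17.23,18.30,7.28,33.42
GLA,73.32,15.39,17.97,20.95,27.14
LAI,62.70,18.90,23.87,1.13,30.83
DSW,94.46,24.43,25.13,3.90,48.91
DLW,86.26,20.72,22.31,0.38,39.65
TDW,94.27,22.83,23.51,4.08,45.66
DH,97.82,4.91,4.96,7.49,10.00
MD,95.63,2.91,2.98,7.01,5.86
GFD,81.86,3.69,4.08,3.06,6.87
NSP,65.48,11.65,14.39,90.46,19.41
PH,77.91,6.75,7.65,9.72,12.27
SL,39.48,7.06,11.23,0.82,9.14
NSS,27.37,4.39,8.40,0.70,4.74
NG,80.41,11.12,12.40,7.25,20.55
HW,80.31,10.08,11.24,8.47,18.60
GY,57.60,10.80,14.24,0.79,16.89
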