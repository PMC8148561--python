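trait,tolerance_before,vif_before,tolerance_after,vif_after
DH,0.036,28.13,0.205,4.89
DM,0.025,40.34,,
GFD,0.053,19.02,0.209,4.77
DSW,0.000,0.00,0.000,0.00
DLW,0.000,0.00,0.000,0.00
TDW,0.000,0.00,0.000,0.00
NSP,0.151,6.61,0.152,6.59
PH,0.255,3.92,0.260,3.85
NL,0.234,4.28,0.234,4.28
LAF,0.130,7.70,0.142,7.07
TLAF,0.129,7.74,0.133,7.52
LAI,0.120,8.33,0.122,8.20
SL,0.182,5.51,0.185,5.41
NSS,0.233,4.29,0.236,4.23
LWC,0.465,2.15,0.465,2.15
RWC,0.300,3.33,0.301,3.33
NG,0.402,2.49,0.417,2.40
HW,0.221,4.54,0.221,4.53
CT,0.176,5.67,0.178,5.62
LEWT,0.463,2.16,0.470,2.13
Pn,0.184,5.43,0.186,5.39
Gs,0.146,6.86,0.159,6.28
Ci,0.109,9.15,0.111,9.02
E,0.100,10.02,0.111,9.03
WUE,0.146,6.83,0.147,6.82
WUEi,0.103,9.67,0.104,9.62
Ls,0.117,8.54,0.127,7.85
GY,0.291,3.44,0.311,3.22
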