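trait,source,df,ms
DH,S,1,8.670
DH,rep(S),4,0.227
DH,I,1,145.60
DH,SxI,1,0.03
DH,rep(IxS),4,3.147
DH,G,24,164.83
DH,SxG,24,0.121
DH,IxG,24,2.721
DH,SxIxG,24,0.079
DH,Error,192,0.926
CT,S,1,0.589
CT,rep(S),4,0.121
CT,I,1,516.17
CT,SxI,1,5.057
CT,rep(IxS),4,0.107
CT,G,24,2.985
CT,SxG,24,0.793
CT,IxG,24,1.692
CT,SxIxG,24,1.014
CT,Error,192,0.078
GY,S,1,3.272
GY,rep(S),4,0.13
GY,I,1,92.596
GY,SxI,1,0.536
GY,rep(IxS),4,0.029
GY,G,24,11.965
GY,SxG,24,0.713
GY,IxG,24,1.714
GY,SxIxG,24,0.302
GY,Error,192,0.078
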