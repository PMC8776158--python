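system,conformer,method,e_vert_eV,e_ad_eV,e00_eV
Fa,A,CC2,,,4.754
Fa,B,CC2,,,4.770
Fa,C,CC2,,,4.767
Fa,D,CC2,,,4.791
GFa,A,CC2,,,4.754
GFa,B',CC2,,,4.771
FFa,A1,CC2,,,4.714
FFa,A2,CC2,,,4.729
FFa,C,CC2,,,4.479
QFa,A,CC2,,,4.803
QFa,C,CC2,,,4.793
Fa,A,wB97X-D,,,5.140
Fa,B,wB97X-D,,,5.161
Fa,C,wB97X-D,,,5.160
Fa,D,wB97X-D,,,5.174
GFa,A,wB97X-D,,,5.178
GFa,B',wB97X-D,,,5.178
FFa,A1,wB97X-D,,,5.154
FFa,A2,wB97X-D,,,5.149
FFa,C,wB97X-D,,,4.219
QFa,A,wB97X-D,,,5.207
QFa,C,wB97X-D,,,5.162
Fa,A,CAM-B3LYP,,,5.168
Fa,B,CAM-B3LYP,,,5.167
Fa,C,CAM-B3LYP,,,5.142
Fa,D,CAM-B3LYP,,,5.192
Fa,A,P1,,,4.953
Fa,B,P1,,,4.972
Fa,C,P1,,,4.971
Fa,D,P1,,,4.983
GFa,A,P1,,,4.867
GFa,B',P1,,,4.979
FFa,A1,P1,,,4.962
FFa,A2,P1,,,4.954
FFa,C,P1,,,4.023
QFa,A,P1,,,5.014
QFa,C,P1,,,4.965
Fa,A,P2,,,4.778
Fa,B,P2,,,4.798
Fa,C,P2,,,4.793
Fa,D,P2,,,4.809
GFa,A,P2,,,4.814
GFa,B',P2,,,4.802
FFa,A1,P2,,,4.771
FFa,A2,P2,,,4.773
FFa,C,P2,,,4.451
QFa,A,P2,,,4.825
QFa,C,P2,,,4.779
Fa,A,experiment,,,4.650
Fa,B,experiment,,,4.663
Fa,C,experiment,,,4.663
Fa,D,experiment,,,4.666
GFa,A,experiment,,,4.648
GFa,B',experiment,,,4.644
FFa,A1,experiment,,,4.648
FFa,A2,experiment,,,4.658
FFa,C,experiment,,,4.630
QFa,A,experiment,,,4.662
QFa,C,experiment,,,4.658
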