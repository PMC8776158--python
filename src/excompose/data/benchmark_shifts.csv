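system,conformer,method,site_label,mode_class,harmonic_cm1,corrected_cm1,experimental_cm1,coupled
Fa,A,CC2,NH_Phe,NH,11,9,-1,false
Fa,A,CC2,NH2_sym,NH2sym,-15,-10,-9,false
Fa,A,CC2,NH2_anti,NH2anti,-18,-9,-6,false
Fa,A,CAM-B3LYP,NH_Phe,NH,-6,,-1,false
Fa,A,CAM-B3LYP,NH2_sym,NH2sym,-29,,-9,false
Fa,A,CAM-B3LYP,NH2_anti,NH2anti,-22,,-6,false
Fa,A,wB97X-D,NH_Phe,NH,10,,-1,false
Fa,A,wB97X-D,NH2_sym,NH2sym,-9,,-9,false
Fa,A,wB97X-D,NH2_anti,NH2anti,-8,,-6,false
Fa,B,CC2,NH_Phe,NH,-44,-37,,false
Fa,B,CC2,NH2_sym,NH2sym,-5,-4,,false
Fa,B,CC2,NH2_anti,NH2anti,-1,-1,,false
Fa,B,CAM-B3LYP,NH_Phe,NH,-44,,,false
Fa,B,CAM-B3LYP,NH2_sym,NH2sym,-5,,,false
Fa,B,CAM-B3LYP,NH2_anti,NH2anti,-2,,,false
Fa,B,wB97X-D,NH_Phe,NH,-25,,,false
Fa,B,wB97X-D,NH2_sym,NH2sym,-6,,,false
Fa,B,wB97X-D,NH2_anti,NH2anti,-3,,,false
Fa,C,CC2,NH_Phe,NH,-44,-37,-24,false
Fa,C,CC2,NH2_sym,NH2sym,-3,-1,-1,false
Fa,C,CC2,NH2_anti,NH2anti,-1,-1,-1,false
Fa,C,CAM-B3LYP,NH_Phe,NH,-38,,-24,false
Fa,C,CAM-B3LYP,NH2_sym,NH2sym,-8,,-1,false
Fa,C,CAM-B3LYP,NH2_anti,NH2anti,-1,,-1,false
Fa,C,wB97X-D,NH_Phe,NH,-44,,-24,false
Fa,C,wB97X-D,NH2_sym,NH2sym,-2,,-1,false
Fa,C,wB97X-D,NH2_anti,NH2anti,2,,-1,false
Fa,D,CC2,NH_Phe,NH,0,0,,false
Fa,D,CC2,NH2_sym,NH2sym,-2,-2,,false
Fa,D,CC2,NH2_anti,NH2anti,0,0,,false
Fa,D,CAM-B3LYP,NH_Phe,NH,-1,,,false
Fa,D,CAM-B3LYP,NH2_sym,NH2sym,0,,,false
Fa,D,CAM-B3LYP,NH2_anti,NH2anti,9,,,false
Fa,D,wB97X-D,NH_Phe,NH,-1,,,false
Fa,D,wB97X-D,NH2_sym,NH2sym,-7,,,false
Fa,D,wB97X-D,NH2_anti,NH2anti,-1,,,false
GFa,A,CC2,NH_Gly,NH,-7,-6,-2,false
GFa,A,CC2,NH_Phe,NH,-18,-15,-18,false
GFa,A,CC2,NH2_sym,NH2sym,-5,-3,3,false
GFa,A,CC2,NH2_anti,NH2anti,0,0,-9,false
GFa,A,wB97X-D,NH_Gly,NH,-2,-2,-2,false
GFa,A,wB97X-D,NH_Phe,NH,-10,-9,-18,true
GFa,A,wB97X-D,NH2_sym,NH2sym,3,2,3,true
GFa,A,wB97X-D,NH2_anti,NH2anti,1,1,-9,false
GFa,B',CC2,NH_Gly,NH,0,0,1,false
GFa,B',CC2,NH_Phe,NH,-21,-18,-18,false
GFa,B',CC2,NH2_sym,NH2sym,1,1,2,false
GFa,B',CC2,NH2_anti,NH2anti,0,0,1,false
GFa,B',wB97X-D,NH_Gly,NH,-1,-1,1,false
GFa,B',wB97X-D,NH_Phe,NH,-4,-4,-18,false
GFa,B',wB97X-D,NH2_sym,NH2sym,1,1,2,false
GFa,B',wB97X-D,NH2_anti,NH2anti,1,1,1,false
FFa,A1,CC2,NH_Phe1,NH,-41,-35,-33,false
FFa,A1,CC2,NH_Phe2,NH,-9,-8,0,false
FFa,A1,CC2,NH2_sym,NH2sym,-4,-3,-1,false
FFa,A1,CC2,NH2_anti,NH2anti,-2,-1,0,false
FFa,A1,wB97X-D,NH_Phe1,NH,-40,-36,-33,false
FFa,A1,wB97X-D,NH_Phe2,NH,-7,-6,0,false
FFa,A1,wB97X-D,NH2_sym,NH2sym,3,2,-1,false
FFa,A1,wB97X-D,NH2_anti,NH2anti,0,0,0,false
FFa,A2,CC2,NH_Phe1,NH,-5,-4,-1,false
FFa,A2,CC2,NH_Phe2,NH,-34,-29,-24,false
FFa,A2,CC2,NH2_sym,NH2sym,-2,-1,-1,false
FFa,A2,CC2,NH2_anti,NH2anti,-1,-1,0,false
FFa,A2,wB97X-D,NH_Phe1,NH,-6,-5,-1,true
FFa,A2,wB97X-D,NH_Phe2,NH,-21,-19,-24,true
FFa,A2,wB97X-D,NH2_sym,NH2sym,3,2,-1,false
FFa,A2,wB97X-D,NH2_anti,NH2anti,0,0,0,false
FFa,C,CC2,NH_Phe1,NH,-12,-10,,false
FFa,C,CC2,NH_Phe2,NH,-74,-63,,false
FFa,C,CC2,NH2_sym,NH2sym,-30,-21,,false
FFa,C,CC2,NH2_anti,NH2anti,-11,-6,,false
FFa,C,wB97X-D,NH_Phe1,NH,-9,-8,,false
FFa,C,wB97X-D,NH_Phe2,NH,-60,-55,,true
FFa,C,wB97X-D,NH2_sym,NH2sym,-21,-15,,true
FFa,C,wB97X-D,NH2_anti,NH2anti,-7,-6,,false
QFa,A,CC2,NH_Gln,NH,-2,-2,,false
QFa,A,CC2,NH_Phe,NH,-12,-10,,false
QFa,A,CC2,NH2_sym_Cterm,NH2sym,5,3,,false
QFa,A,CC2,NH2_anti_Cterm,NH2anti,8,4,,false
QFa,A,CC2,NH2_sym_chain,NH2sym,-2,-1,,false
QFa,A,CC2,NH2_anti_chain,NH2anti,-2,-1,,false
QFa,A,wB97X-D,NH_Gln,NH,-6,-5,,false
QFa,A,wB97X-D,NH_Phe,NH,-22,-20,,false
QFa,A,wB97X-D,NH2_sym_Cterm,NH2sym,-2,-1,,false
QFa,A,wB97X-D,NH2_anti_Cterm,NH2anti,0,0,,false
QFa,A,wB97X-D,NH2_sym_chain,NH2sym,0,0,,false
QFa,A,wB97X-D,NH2_anti_chain,NH2anti,0,0,,false
QFa,C,CC2,NH_Gln,NH,-9,-8,,false
QFa,C,CC2,NH_Phe,NH,-16,-14,,false
QFa,C,CC2,NH2_sym_Cterm,NH2sym,-2,-1,,false
QFa,C,CC2,NH2_anti_Cterm,NH2anti,0,0,,false
QFa,C,CC2,NH2_sym_chain,NH2sym,-1,-1,,false
QFa,C,CC2,NH2_anti_chain,NH2anti,1,1,,false
QFa,C,wB97X-D,NH_Gln,NH,-9,-8,,false
QFa,C,wB97X-D,NH_Phe,NH,-32,-29,,false
QFa,C,wB97X-D,NH2_sym_Cterm,NH2sym,-2,-1,,false
QFa,C,wB97X-D,NH2_anti_Cterm,NH2anti,0,0,,false
QFa,C,wB97X-D,NH2_sym_chain,NH2sym,-2,-1,,false
QFa,C,wB97X-D,NH2_anti_chain,NH2anti,3,2,,false
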