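test_method,reference_method,group,n,mae_eV,me_eV
wB97X-D,CC2,all,11,0.39,0.34
wB97X-D,CC2,residue1,4,0.39,0.39
wB97X-D,CC2,residue2,7,0.39,0.31
wB97X-D,experiment,all,11,0.50,0.43
wB97X-D,experiment,residue1,4,0.50,0.50
wB97X-D,experiment,residue2,7,0.50,0.39
P1,CC2,all,11,0.22,0.14
P1,CC2,residue1,4,0.20,0.20
P1,CC2,residue2,7,0.23,0.10
P1,experiment,all,11,0.33,0.22
P1,experiment,residue1,4,0.31,0.31
P1,experiment,residue2,7,0.35,0.17
P2,CC2,all,11,0.03,0.02
P2,CC2,residue1,4,0.02,0.02
P2,CC2,residue2,7,0.04,0.02
P2,experiment,all,11,0.14,0.11
P2,experiment,residue1,4,0.13,0.13
P2,experiment,residue2,7,0.15,0.10
CC2,experiment,all,11,0.11,0.08
CC2,experiment,residue1,4,0.11,0.11
CC2,experiment,residue2,7,0.11,0.07
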