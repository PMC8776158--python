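test_method,reference_method,group,mae_eV,me_eV
wB97X-D,CC2,residue1,0.40,0.40
wB97X-D,CC2,all,0.39,0.35
wB97X-D,experiment,residue1,0.50,0.50
wB97X-D,experiment,all,0.50,0.43
P1,CC2,all,0.15,0.14
P1,experiment,all,0.33,0.22
P2,CC2,all,0.03,0.02
P2,experiment,all,0.14,0.11
CC2,experiment,residue1,0.11,0.11
P1,CC2,residue1,0.20,0.20
P1,CC2,residue2,0.23,0.10
P1,experiment,residue1,0.31,0.31
P1,experiment,residue2,0.34,0.17
P2,CC2,residue1,0.02,0.02
P2,CC2,residue2,0.03,0.02
P2,experiment,residue1,0.14,0.14
P2,experiment,residue2,0.14,0.09
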