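name = P2
e_vert_source = CC2
dd_ad_source = CC2
dd_00_source = wB97X-D
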