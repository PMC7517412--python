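lobe,column,middle,elderly,printed_ratio
frontal,total,0.3986,0.3686,92.4
frontal,left,0.4552,0.4168,91.6
frontal,right,0.3421,0.3211,93.8
temporal,total,0.3351,0.4239,126.5
temporal,left,0.3127,0.3867,123.7
temporal,right,0.3575,0.4488,125.6
parietal,total,0.3779,0.3378,89.4
parietal,left,0.426,0.3576,83.9
parietal,right,0.3298,0.3195,96.9
occipital,total,0.3876,0.4642,119.8
occipital,left,0.3551,0.4309,121.3
occipital,right,0.4207,0.5012,119.1
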