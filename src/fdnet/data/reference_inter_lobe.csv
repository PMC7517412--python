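lobe,column,middle,elderly,printed_ratio
frontal,total,0.7119,0.6345,89.1
frontal,left,0.7131,0.636,89.2
frontal,right,0.7106,0.633,89.1
temporal,total,0.7088,0.6546,92.3
temporal,left,0.7087,0.658,92.8
temporal,right,0.7089,0.6512,91.9
parietal,total,0.7104,0.6265,88.1
parietal,left,0.7099,0.6405,90.2
parietal,right,0.7108,0.6125,86.1
occipital,total,0.7134,0.6341,88.8
occipital,left,0.7137,0.6383,89.4
occipital,right,0.7131,0.630,88.4
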