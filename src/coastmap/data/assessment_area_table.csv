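class,area_ha,users_accuracy
black mangrove,2158.5,0.85
invasive species,16.4,0.91
buttonwood/glycophyte,429.8,0.91
buttonwood/halophyte,653.2,1.00
halophyte prairie,899.5,0.74
hardwood hammock,239.2,0.62
red mangrove,1493.0,0.89
white mangrove,511.6,0.91
mud flat,253.7,0.89
water,408.6,0.89
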