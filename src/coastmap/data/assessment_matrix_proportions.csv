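map_class,black mangrove,buttonwood/glycophyte,buttonwood/halophyte,water,halophyte prairie,hardwood hammock,invasive species,mud flat,red mangrove,white mangrove
black mangrove,0.85,0.08,0.02,0.00,0.00,0.00,0.00,0.00,0.04,0.02
buttonwood/glycophyte,0.06,0.89,0.06,0.00,0.00,0.00,0.00,0.00,0.00,0.00
buttonwood/halophyte,0.00,0.06,0.91,0.00,0.04,0.00,0.00,0.00,0.00,0.00
water,0.00,0.00,0.00,1.00,0.00,0.00,0.00,0.00,0.00,0.00
halophyte prairie,0.02,0.04,0.02,0.00,0.89,0.00,0.00,0.04,0.00,0.00
hardwood hammock,0.06,0.00,0.11,0.00,0.02,0.74,0.04,0.00,0.04,0.00
invasive species,0.02,0.00,0.15,0.00,0.02,0.06,0.62,0.00,0.13,0.00
mud flat,0.02,0.00,0.00,0.06,0.04,0.00,0.00,0.89,0.00,0.00
red mangrove,0.08,0.00,0.00,0.00,0.00,0.02,0.00,0.00,0.89,0.02
white mangrove,0.00,0.02,0.08,0.00,0.00,0.00,0.00,0.00,0.00,0.91
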