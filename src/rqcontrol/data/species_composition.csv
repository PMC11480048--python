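species,c,h,o,n
glucose,1,2.0,1.0,0.0
biomass,1,1.761,0.636,0.143
ethanol,1,3.0,0.5,0.0
arabitol,1,2.4,1.0,0.0
succinate,1,1.5,1.0,0.0
co2,1,0.0,2.0,0.0
o2,0,0.0,2.0,0.0
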