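year,construction,cultivated,forest,shrub,grassland,wetland
2025,208.34,16507.03,150877.57,3853.53,171672.3,279.04
2030,228.3,16579.81,151503.05,3871.71,171410.52,161.98
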