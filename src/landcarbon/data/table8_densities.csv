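year,cultivated,forest,shrub,grassland,lake,wetland
2025,544.02,554.14,477.14,265.51,149.1,184.81
2030,558.65,556.86,494.88,267.01,149.1,184.81
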