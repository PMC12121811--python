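year,construction,cultivated,forest,shrub,grassland,wetland
2025,198.27,14179.34,134407.22,3074.83,149164.5,436.88
2030,229.55,13734.98,135526.69,2910.03,148164.52,537.72
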