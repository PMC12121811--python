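year,construction,cultivated,forest,shrub,grassland,wetland,lake,ice_snow,wasteland
2025,203.31,15343.19,142642.4,3464.18,160418.4,357.96,1271.14,3443.62,1355.81
2030,228.92,15157.39,143514.87,3390.87,159787.52,349.85,1271.14,3443.62,1355.81
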