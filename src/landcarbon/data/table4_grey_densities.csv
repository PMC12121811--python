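year,cultivated,forest,shrub,grassland,lake,wetland
2025,574.6,540.4,485.0,257.46,205.08,237.26
2030,612.91,545.85,520.47,260.46,231.92,264.97
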