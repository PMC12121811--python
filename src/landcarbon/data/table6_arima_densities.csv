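year,cultivated,forest,shrub,grassland,lake,wetland
2025,513.44,567.87,469.28,273.56,205.13,229.52
2030,504.38,567.87,469.28,273.56,229.92,229.52
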