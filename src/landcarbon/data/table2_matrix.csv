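from_class,cultivated,forest,shrub,grassland,lake,ice_snow,wasteland,construction,wetland
cultivated,0.8611,0.1008,0.0052,0.0294,0.0019,0.0,0.0,0.0016,0.0
forest,0.009,0.9852,0.0056,0.0001,0.0,0.0,0.0,0.0001,0.0
shrub,0.0131,0.1493,0.6479,0.1761,0.0,0.0,0.0,0.0,0.0
grassland,0.0029,0.0061,0.0024,0.9802,0.0005,0.0,0.0069,0.0,0.0011
lake,0.003,0.0031,0.0,0.1299,0.7681,0.0002,0.0893,0.0008,0.0
ice_snow,0.0,0.0,0.0,0.0196,0.007,0.6892,0.2821,0.0,0.0
wasteland,0.0,0.0004,0.0,0.1709,0.0036,0.0795,0.7443,0.0,0.0
construction,0.0,0.0,0.0,0.0001,0.0633,0.0,0.0,0.9366,0.0
wetland,0.0002,0.0004,0.0001,0.2738,0.0053,0.0,0.0,0.0,0.6969
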