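year,cultivated,forest,shrub,grassland,lake,wetland,total
2021,834.107,7376.8004,163.6874,3833.9252,18.9521,6.0819,12133.554
2022,833.5606,7396.254,164.2869,3540.6517,18.9521,5.1716,11958.8769
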