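year,cultivated,forest,shrub,grassland,lake,wetland,impact_t,total
2025,834.7002,7904.386,165.2899,4259.2689,6.6155,18.9527,-20754,13187.1378
2030,846.7676,7991.7691,167.8074,4266.4866,6.4656,18.9527,-30837,13295.1653
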