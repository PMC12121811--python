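year,class,zr_t,zc_t,subtotal_t
2025,construction,-21411,1915,-19496
2025,cultivated,121148,-140193,-19045
2025,forest,339850,-86510,253340
2025,shrub,69537,-86246,-16709
2025,grassland,-152274,176012,23738
2025,wasteland,-310814,62549,-248265
2025,ice_snow,-38,21515,21477
2025,lake,-14678,5234,-9444
2025,wetland,-14240,7892,-6349
2030,construction,-21692,2156,-19535
2030,cultivated,141865,-163057,-21192
2030,forest,313132,-59662,253470
2030,shrub,77103,-101852,-24750
2030,grassland,-162945,186785,23839
2030,wasteland,-311312,62898,-248414
2030,ice_snow,-38,21616,21578
2030,lake,-14799,5556,-9243
2030,wetland,-14448,7858,-6590
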