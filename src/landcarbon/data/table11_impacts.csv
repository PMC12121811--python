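year,class,zr_t,zc_t,subtotal_t
2021,construction,-21374,1654,-19720
2021,cultivated,113429,-132962,-19533
2021,forest,351906,-100887,251019
2021,shrub,265,-74092,-73828
2021,grassland,-147450,169303,21853
2021,wasteland,-309065,62274,-246791
2021,ice_snow,-38,21435,21397
2021,lake,-14765,5005,-9759
2021,wetland,-14011,7148,-6863
2022,construction,-21385,1698,-19687
2022,cultivated,119775,-139091,-19316
2022,forest,361451,-98444,263008
2022,shrub,8292,-84758,-76466
2022,grassland,-169647,209267,39620
2022,wasteland,-295729,59521,-236208
2022,ice_snow,-38,20633,20595
2022,lake,-13755,3058,-10697
2022,wetland,-11908,5168,-6741
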