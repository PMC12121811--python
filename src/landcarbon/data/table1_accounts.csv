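year,class,area_km2,seq_1e4t,density_gm2
2000,construction,107,,
2000,cultivated,15887,647,407
2000,forest,128841,5889,457
2000,shrub,3317,119,359
2000,grassland,154516,3540,229
2000,lake,977,14,141
2000,wetland,404,8,201
2001,construction,108,,
2001,cultivated,15927,631,396
2001,forest,128973,6033,468
2001,shrub,3200,118,369
2001,grassland,154615,3714,240
2001,lake,1030,14,139
2001,wetland,155,3,199
2002,construction,110,,
2002,cultivated,15831,704,445
2002,forest,129183,6291,487
2002,shrub,3255,124,382
2002,grassland,154509,3860,250
2002,lake,1030,15,148
2002,wetland,140,3,215
2003,construction,111,,
2003,cultivated,15613,696,446
2003,forest,129681,6312,487
2003,shrub,3234,120,372
2003,grassland,154101,3713,241
2003,lake,1073,15,144
2003,wetland,126,2,180
2004,construction,115,,
2004,cultivated,15466,688,445
2004,forest,130134,6396,492
2004,shrub,3182,114,358
2004,grassland,153671,3519,229
2004,lake,1252,17,132
2004,wetland,105,2,185
2005,construction,119,,
2005,cultivated,15248,658,432
2005,forest,130640,6127,469
2005,shrub,3129,123,392
2005,grassland,153206,3787,247
2005,lake,1442,19,134
2005,wetland,99,2,188
2006,construction,120,,
2006,cultivated,15224,671,441
2006,forest,130897,6551,501
2006,shrub,3043,131,432
2006,grassland,153034,4208,275
2006,lake,1477,21,145
2006,wetland,108,2,186
2007,construction,122,,
2007,cultivated,15229,682,448
2007,forest,130998,6423,490
2007,shrub,3092,129,418
2007,grassland,152886,3879,254
2007,lake,1515,21,137
2007,wetland,95,2,170
2008,construction,123,,
2008,cultivated,15098,722,479
2008,forest,131314,6362,485
2008,shrub,3197,131,411
2008,grassland,152665,3626,237
2008,lake,1503,21,137
2008,wetland,96,1,156
2009,construction,126,,
2009,cultivated,15216,728,479
2009,forest,131341,6582,501
2009,shrub,3356,141,420
2009,grassland,152478,4016,263
2009,lake,1452,22,149
2009,wetland,128,2,149
2010,construction,131,,
2010,cultivated,15346,690,450
2010,forest,131534,6532,497
2010,shrub,3457,135,389
2010,grassland,152189,3894,256
2010,lake,1456,19,134
2010,wetland,186,3,159
2011,construction,133,,
2011,cultivated,15309,699,456
2011,forest,131617,6946,528
2011,shrub,3483,142,408
2011,grassland,152097,3959,260
2011,lake,1425,20,142
2011,wetland,243,4,175
2012,construction,135,,
2012,cultivated,15246,726,476
2012,forest,131737,6449,490
2012,shrub,3506,130,370
2012,grassland,151988,3543,233
2012,lake,1404,18,130
2012,wetland,279,5,162
2013,construction,138,,
2013,cultivated,15380,775,504
2013,forest,131698,7325,556
2013,shrub,3594,155,431
2013,grassland,151206,4030,267
2013,lake,1389,22,161
2013,wetland,263,5,198
2014,construction,142,,
2014,cultivated,15458,793,513
2014,forest,131652,6946,528
2014,shrub,3621,149,411
2014,grassland,151008,3652,242
2014,lake,1350,20,148
2014,wetland,239,4,172
2015,construction,148,,
2015,cultivated,15307,822,537
2015,forest,131918,7216,547
2015,shrub,3470,148,426
2015,grassland,151255,3728,246
2015,lake,1260,20,159
2015,wetland,163,3,165
2016,construction,154,,
2016,cultivated,15043,765,508
2016,forest,132393,7209,545
2016,shrub,3332,146,439
2016,grassland,151321,3961,262
2016,lake,1187,19,164
2016,wetland,155,3,193
2017,construction,158,,
2017,cultivated,14895,771,518
2017,forest,132591,6954,525
2017,shrub,3413,146,429
2017,grassland,151046,3723,246
2017,lake,1177,19,163
2017,wetland,167,3,188
2018,construction,162,,
2018,cultivated,14865,751,506
2018,forest,132728,6715,506
2018,shrub,3264,139,425
2018,grassland,150704,3601,239
2018,lake,1114,18,163
2018,wetland,290,6,221
2019,construction,166,,
2019,cultivated,14664,780,532
2019,forest,133097,7273,546
2019,shrub,3103,144,464
2019,grassland,150194,3990,266
2019,lake,1078,20,183
2019,wetland,433,10,229
2020,construction,171,,
2020,cultivated,14494,777,536
2020,forest,133641,7115,532
2020,shrub,3370,149,442
2020,grassland,150024,3865,258
2020,lake,1103,20,178
2020,wetland,428,8,190
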