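tag_id,sex,maturity,tl_cm,tagging_year,tagging_island,tag_life_days,detection_period_days,n_detections,n_detection_days,n_detection_months,ri,cr,mld_km,n_receivers,n_islands,primary_sfi_pct
48033,F,M,196,2010,GC,1167,15,83,15,1,0.0129,Pass.-by,32.7,7,1,74
48035,F,M,192,2010,LC,1167,4,4,1,1,0.0009,Pass.-by,114.5,1,1,100
48039,F,IM,159,2010,LC,1167,1159,22,15,5,0.0129,Ps.-res.,7.1,1,1,100
48042,F,IM,138,2010,LC,1167,6,54,5,1,0.0043,Pass.-by,18.4,3,1,54
32353,M,M,156,2011,CB,1262,1179,2094,254,25,0.2013,Ps.-res.,22.3,5,1,70
32354,F,IM,170,2011,CB,1262,1063,24220,232,18,0.1838,Ps.-res.,20.0,4,1,100
32355,M,M,171,2011,CB,1262,97,82,9,3,0.0071,Ps.-res.,142.2,3,3,99
32357,F,IM,133,2011,CB,1262,8,402,6,1,0.0048,Pass.-by,4.3,1,1,100
32360,F,IM,175,2011,LC,1262,78,112,13,2,0.0103,Trans.,28.9,5,2,59
48017,M,IM,142,2011,LC,1167,12,44,7,1,0.0060,Pass.-by,18.6,3,2,67
48020,M,M,159,2011,GC,1167,86,53,8,2,0.0069,Trans.,0.8,1,1,100
28955,F,M,195,2012,GC,1237,1037,4206,595,35,0.4810,Resident,148.2,11,2,100
32367,F,M,190,2012,LC,1262,6,3,1,1,0.0008,Pass.-by,2.2,1,1,100
32361,M,M,159,2013,LC,1262,1598,1711,172,32,0.1363,Ps.-res.,29.9,20,2,96
32364,M,M,160,2013,LC,1262,429,3916,151,13,0.1197,Resident,42.4,9,2,80
32366,F,IM,103,2013,LC,1262,691,1249,114,20,0.0903,Ps.-res.,3.6,2,1,99
32369,M,M,169,2013,LC,1262,1,3,1,1,0.0008,Pass.-by,0.9,1,1,100
32352,M,IM,120,2015,GC,1262,14,23,5,2,0.0040,Pass.-by,6.0,1,1,100
32359,F,M,191,2015,GC,1262,13,5,3,1,0.0024,Pass.-by,12.9,1,1,100
22285,F,IM,132,2016,LC,1915,10,683,7,1,0.0037,Pass.-by,8.2,2,1,75
22291,M,M,156,2016,LC,1915,539,17088,544,20,0.2841,Resident,19.7,20,1,100
22292,M,M,172,2016,LC,1915,24,44,9,1,0.0047,Pass.-by,8.6,4,1,71
22295,M,M,152,2016,LC,1915,15,2899,15,1,0.0078,Pass.-by,0.9,2,1,100
22296,F,M,181,2016,GC,1915,3,59,2,1,0.0010,Pass.-by,1.2,1,1,100
32371,F,IM,169,2016,LC,1262,18,223,17,1,0.0135,Pass.-by,4.0,4,1,80
43700,M,IM,94,2016,LC,481,5,57,3,1,0.0062,Pass.-by,8.2,3,1,56
43701,M,IM,98,2016,LC,481,546,3415,200,18,0.4158,Resident,17.0,16,1,82
43702,M,IM,83,2016,LC,481,5,22,2,1,0.0042,Pass.-by,8.2,2,1,59
45050,M,IM,76,2016,LC,480,1,21,1,1,0.0021,Pass.-by,1.9,1,1,100
45051,M,IM,102,2016,LC,480,6,201,6,1,0.0125,Pass.-by,1.0,2,1,96
22301,M,M,167,2017,LC,1915,88,4,1,2,0.0005,Trans.,39.4,1,1,100
22305,M,M,183,2017,LC,1915,282,6915,225,11,0.1175,Resident,16.3,8,1,40
43695,F,IM,83,2017,LC,481,4,126,4,1,0.0083,Pass.-by,1.9,5,1,85
22315,M,M,152,2019,LC,1915,8,698,8,2,0.0042,Pass.-by,2.3,2,1,100
22316,M,M,170,2019,LC,1915,13,1059,12,2,0.0063,Pass.-by,7.4,5,1,77
22324,F,M,190,2019,GC,1915,16,2037,15,1,0.0078,Pass.-by,3.8,2,1,100
22325,M,M,185,2019,GC,1915,28,2229,26,2,0.0136,Pass.-by,3.8,2,1,99
45052,F,IM,89,2019,LC,480,66,525,34,4,0.0708,Resident,10.4,5,1,97
45053,M,IM,105,2019,LC,480,62,1060,47,3,0.0979,Resident,4.0,3,1,52
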