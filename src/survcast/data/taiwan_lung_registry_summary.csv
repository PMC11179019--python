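# Annual counts of newly diagnosed lung cancer in Taiwan, 1997-2017,
# by sex, age group, histological type, and stage at diagnosis, as
# published in Taiwan Cancer Registry-based reporting.  Stage counts
# are available from 2007 onward; staged totals fall short of the year
# total by the patients with unknown stage.
year,male,female,age_lt55,age_55_64,age_65_74,age_ge75,adeno,scc,sclc,other,stage_i,stage_ii,stage_iii,stage_iv,total
1997,4041,1721,850,1186,2248,1478,2202,1448,503,1609,,,,,5762
1998,4425,1963,926,1253,2473,1736,2505,1589,550,1744,,,,,6388
1999,4681,2114,1015,1249,2599,1932,2790,1667,607,1731,,,,,6795
2000,4634,2013,972,1197,2509,1969,2789,1637,625,1596,,,,,6647
2001,4808,2265,1124,1292,2444,2213,3136,1594,627,1716,,,,,7073
2002,4788,2316,1134,1260,2427,2283,3087,1536,632,1822,,,,,7104
2003,5468,2720,1288,1421,2677,2802,3688,1735,776,1989,,,,,8188
2004,5746,2727,1315,1470,2619,3069,3811,1833,767,2062,,,,,8473
2005,5627,2954,1453,1491,2545,3092,4205,1759,751,1866,,,,,8581
2006,6064,3150,1468,1621,2644,3481,4664,1825,844,1881,,,,,9214
2007,6249,3424,1627,1749,2796,3501,5058,1801,856,1958,927,223,1840,4093,9673
2008,6625,3633,1600,1948,2873,3837,5578,1813,981,1886,959,255,1843,4148,10258
2009,6555,3902,1638,2177,2789,3853,5945,1794,877,1841,1390,267,2290,5345,10457
2010,6824,3965,1767,2273,2787,3962,6174,1976,901,1738,1298,462,1731,5719,10789
2011,7071,4451,1908,2570,2901,4143,7011,1925,876,1710,1324,422,1662,5797,11522
2012,6971,4499,1871,2761,2908,3930,7162,1871,866,1571,1744,435,1700,6009,11470
2013,7312,4944,2082,3012,3113,4049,7851,1904,938,1563,1966,448,1657,6015,12256
2014,7380,5230,2067,3192,3192,4159,8156,1920,943,1591,2174,511,1658,6355,12610
2015,7715,5660,2181,3432,3473,4289,8920,1906,959,1590,2647,500,1700,6395,13375
2016,7889,5903,2250,3534,3724,4284,9333,1911,944,1554,3088,513,1670,6433,13792
2017,8008,6521,2451,3842,3950,4286,10223,1856,984,1466,3659,499,1784,6556,14529
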