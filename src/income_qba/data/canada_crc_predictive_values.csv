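stratum,observed_q,true_q,estimate,lo,hi
0,1,1,0.3127,0.2936,0.3326
0,1,2,0.2651,0.2470,0.2841
0,1,3,0.1857,0.1700,0.2026
0,1,4,0.1465,0.1323,0.1619
0,1,5,0.0899,0.0787,0.1025
0,2,1,0.1762,0.1617,0.1917
0,2,2,0.2414,0.2249,0.2587
0,2,3,0.2278,0.2117,0.2449
0,2,4,0.1984,0.1830,0.2146
0,2,5,0.1562,0.1424,0.1711
0,3,1,0.1578,0.1441,0.1725
0,3,2,0.2228,0.2070,0.2396
0,3,3,0.2249,0.2089,0.2416
0,3,4,0.2132,0.1976,0.2297
0,3,5,0.1813,0.1668,0.1969
0,4,1,0.1190,0.1070,0.1322
0,4,2,0.1799,0.1654,0.1954
0,4,3,0.2276,0.2116,0.2443
0,4,4,0.2336,0.2175,0.2505
0,4,5,0.2400,0.2237,0.2570
0,5,1,0.0836,0.0735,0.0950
0,5,2,0.1427,0.1296,0.1569
0,5,3,0.1819,0.1673,0.1975
0,5,4,0.2225,0.2066,0.2392
0,5,5,0.3693,0.3505,0.3884
1,1,1,0.3662,0.3448,0.3880
1,1,2,0.2756,0.2561,0.2960
1,1,3,0.1683,0.1523,0.1857
1,1,4,0.1152,0.1017,0.1301
1,1,5,0.0747,0.0640,0.0872
1,2,1,0.2480,0.2293,0.2678
1,2,2,0.2945,0.2746,0.3152
1,2,3,0.2001,0.1828,0.2185
1,2,4,0.1604,0.1447,0.1774
1,2,5,0.0970,0.0847,0.1109
1,3,1,0.2030,0.1851,0.2223
1,3,2,0.2691,0.2490,0.2901
1,3,3,0.2076,0.1894,0.2270
1,3,4,0.1816,0.1644,0.2001
1,3,5,0.1388,0.1236,0.1554
1,4,1,0.1708,0.1533,0.1898
1,4,2,0.2334,0.2134,0.2546
1,4,3,0.2137,0.1944,0.2343
1,4,4,0.2064,0.1875,0.2268
1,4,5,0.1757,0.1584,0.1948
1,5,1,0.1312,0.1158,0.1482
1,5,2,0.1965,0.1780,0.2163
1,5,3,0.1925,0.1741,0.2122
1,5,4,0.2030,0.1843,0.2231
1,5,5,0.2769,0.2557,0.2991
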