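sample,gastrodin,p-hydroxybenzyl alcohol,parishin E,p-hydroxy benzaldehyde,parishin B,parishin C,parishin A
S1,1797.1,2249.5,2337.8,217.4,2263.6,420.7,4340.3
S2,1470.2,2144.3,2523.4,227.6,2526.6,462.2,4561.9
S3,623.8,4536.4,1528.4,301.7,1017,280.3,1487.8
S4,1325.1,1516.1,1412.1,116.7,1906.9,402.8,3150
S5,1659.3,2123.3,1991.3,111.9,2141.7,383.4,4006.4
S6,1161,1463.7,3734.3,108.1,1867.1,390.2,3167.6
S7,1492.8,663.8,2991.6,85.8,1818.7,392.5,3473.5
S8,1470.9,823.8,1573.2,127.1,2231.8,546.3,5104.3
S9,1898,1876.6,2572.7,82,2629.1,595.9,4430.8
S10,3816.6,136.2,1316.2,110.1,2663.3,441.9,3383.6
S11,2353.9,970.8,1563.7,131.9,3073.4,789.5,9224.6
S12,1794,830,2577.2,45.7,2141.8,101.1,3845.8
S13,2344.5,572.4,2363.1,57.6,2039.1,499.2,5019.1
S14,1369.4,427.8,1961.6,41.9,2408.9,622.1,5512.4
S15,2177.5,1270.2,2076.6,56.6,3133.4,791.2,8184.9
S16,3322.1,108.1,1240.9,73.1,1935.1,357.8,2127.8
S17,1081.8,322.8,2365,104.7,2363.6,500.7,5062.6
S18,1893.7,270.9,1719.4,78.3,2475.6,823,6072.7
S19,380.4,4012.7,1414.3,617.3,781.5,136.4,1789.1
S20,300.9,3287.7,878.9,564,479.5,102.3,687.1
S21,2175.1,1076.8,2057.2,143.7,2826.4,94.7,6278.5
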