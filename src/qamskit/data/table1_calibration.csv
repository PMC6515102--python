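analyte,slope,intercept,range_low,range_high,r_squared,lod,loq
gastrodin,18634,-264.07,1.906,6.483,0.9997,0.042,0.139
p-hydroxybenzyl alcohol,39300,42.955,0.075,1.773,0.9995,0.001,0.003
parishin E,14141,142.93,2.273,7.052,0.9997,0.037,0.122
p-hydroxy benzaldehyde,52536,7.9174,0.079,2.588,1.0000,0.001,0.005
parishin B,20791,6.7746,1.450,5.190,1.0000,0.004,0.015
parishin C,31240,-335.24,0.286,0.356,0.9997,0.005,0.015
parishin A,11769,-100.83,0.181,19.301,0.9995,0.020,0.070
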