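component,eigenvalue,pct_variance,cum_pct,extraction_total,extraction_pct,extraction_cum,rotation_total,rotation_pct,rotation_cum
1,2.717,45.282,45.282,2.717,45.282,45.282,2.280,38.006,38.006
2,1.836,30.596,75.878,1.836,30.596,75.878,1.663,27.720,65.727
3,0.804,13.405,89.283,0.804,13.405,89.283,1.413,23.556,89.283
4,0.414,6.898,96.181,,,,,,
5,0.168,2.803,98.984,,,,,,
6,0.061,1.016,100.000,,,,,,
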