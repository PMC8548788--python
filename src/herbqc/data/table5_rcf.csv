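flow_rate_ml_min,column_temp_c,chlorogenic_acid,caffeic_acid,p_coumaric_acid,luteolin,apigenin
0.6,30,2.7026,0.8157,1.2796,0.3808,0.5750
0.6,35,2.7050,0.8162,1.2833,0.3862,0.5675
0.6,40,2.7036,0.8135,1.2842,0.3851,0.5759
0.8,30,2.7112,0.8198,1.2787,0.3823,0.5746
0.8,35,2.7033,0.8173,1.2820,0.3811,0.5802
0.8,40,2.6997,0.8187,1.2829,0.3833,0.5776
1.0,30,2.7028,0.8190,1.2814,0.3824,0.5754
1.0,35,2.7031,0.8211,1.2835,0.3835,0.5721
1.0,40,2.6981,0.8179,1.2830,0.3836,0.5760
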