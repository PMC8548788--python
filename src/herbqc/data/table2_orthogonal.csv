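run,solid_liquid_ratio,solvent_concentration,extraction_time_min,column_temperature_c,total
1,1:25,60%,15,30,17.013
2,1:25,70%,30,35,18.898
3,1:25,80%,45,40,15.245
4,1:30,60%,30,40,19.402
5,1:30,70%,45,30,19.983
6,1:30,80%,15,35,16.974
7,1:35,60%,45,35,18.930
8,1:35,70%,15,40,19.912
9,1:35,80%,30,30,16.176
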