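compound,slope,intercept,r_squared,range_low_ug_ml,range_high_ug_ml
chlorogenic_acid,10.69,48.25,0.9991,7.5,100.0
caffeic_acid,35.03,-56.98,0.9991,2.5,163.0
p_coumaric_acid,21.53,-76.26,0.9993,1.5,200.0
cichoric_acid,29.75,23.08,0.9990,75.0,525.0
luteolin,91.02,-28.30,0.9997,2.0,175.0
apigenin,22.08,49.15,0.9996,1.6,87.50
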