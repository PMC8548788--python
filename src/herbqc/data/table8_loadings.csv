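compound,rotated_f1,rotated_f2,rotated_f3,coef_f1,coef_f2,coef_f3
chlorogenic_acid,-0.176,0.806,0.428,-0.006,0.453,0.070
caffeic_acid,0.591,-0.034,-0.686,0.216,0.269,-0.575
p_coumaric_acid,0.192,0.338,0.869,0.171,-0.062,0.685
cichoric_acid,-0.043,0.939,0.063,0.034,0.704,-0.307
luteolin,0.977,-0.097,0.004,0.441,-0.026,0.115
apigenin,0.953,-0.081,-0.004,0.430,-0.012,0.100
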