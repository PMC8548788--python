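compound,precision_rsd,stability_rsd,repeatability_rsd,recovery_mean,recovery_rsd
chlorogenic_acid,1.76,1.23,2.05,99.82,1.15
caffeic_acid,1.66,1.40,0.47,100.25,2.04
p_coumaric_acid,1.08,1.35,2.11,99.89,1.51
cichoric_acid,1.30,2.45,1.66,101.24,2.37
luteolin,2.03,2.21,1.24,103.33,2.10
apigenin,0.89,1.32,3.42,100.10,2.25
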