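batch,cichoric_acid_esm,chlorogenic_acid_esm,chlorogenic_acid_qams,chlorogenic_acid_re,chlorogenic_acid_rsd,caffeic_acid_esm,caffeic_acid_qams,caffeic_acid_re,caffeic_acid_rsd,p_coumaric_acid_esm,p_coumaric_acid_qams,p_coumaric_acid_re,p_coumaric_acid_rsd,luteolin_esm,luteolin_qams,luteolin_re,luteolin_rsd,apigenin_esm,apigenin_qams,apigenin_re,apigenin_rsd
S1,14.148,1.203,1.209,0.50,0.35,0.250,0.249,-0.40,0.28,0.249,0.249,0.00,0.21,0.003,0.003,0.00,0.33,0.015,0.015,0.00,0.77
S2,5.136,0.678,0.654,-3.54,2.55,0.147,0.150,2.04,1.43,0.282,0.285,1.06,0.75,0.006,0.006,0.00,0.98,0.003,0.003,0.00,0.43
S3,9.177,0.600,0.603,0.50,0.35,0.329,0.324,-1.52,1.08,0.075,0.078,4.00,2.77,0.009,0.009,0.00,0.40,0.006,0.006,0.00,0.15
S4,14.949,0.963,0.948,-1.56,1.11,0.423,0.426,0.71,0.50,0.276,0.276,0.00,0.59,0.015,0.015,0.00,0.65,0.003,0.003,0.00,0.56
S5,2.856,0.225,0.228,1.33,0.94,0.621,0.624,0.48,0.34,0.060,0.060,0.00,0.23,0.162,0.162,0.00,0.71,0.093,0.090,-3.23,2.32
S6,11.298,0.327,0.342,4.59,3.17,0.369,0.375,1.63,1.14,0.054,0.054,0.00,0.71,0.012,0.012,0.00,0.67,0.006,0.006,0.00,0.49
S7,9.114,0.717,0.702,-2.09,1.49,0.388,0.381,-1.80,1.29,0.309,0.312,0.97,0.68,0.093,0.090,-3.23,2.32,0.018,0.018,0.00,0.29
S8,8.643,0.945,0.936,-0.95,0.68,0.126,0.129,2.38,1.66,0.276,0.282,2.17,1.52,0.003,0.003,0.00,1.32,0.012,0.012,0.00,0.78
S9,5.508,0.648,0.636,-1.85,1.32,0.122,0.120,-1.64,1.17,0.288,0.291,1.04,0.73,0.009,0.009,0.00,0.46,0.003,0.003,0.00,0.45
S10,5.199,0.498,0.498,0.00,0.10,0.699,0.711,1.72,1.20,0.201,0.198,-1.49,1.06,0.102,0.099,-2.94,2.11,0.087,0.090,3.45,2.40
S11,3.135,0.657,0.642,-2.28,1.63,0.540,0.531,-1.67,1.19,0.222,0.219,-1.35,0.96,0.075,0.078,4.00,2.77,0.093,0.090,-3.23,2.32
S12,7.890,0.789,0.759,-3.80,2.74,0.784,0.792,1.02,0.72,0.117,0.114,-2.56,1.84,0.015,0.015,0.00,0.74,0.003,0.003,0.00,0.38
S13,12.723,1.332,1.296,-2.70,1.94,0.309,0.303,-1.94,1.39,0.285,0.279,-2.11,1.50,0.057,0.057,0.00,0.58,0.006,0.006,0.00,1.42
S14,15.453,0.966,0.975,0.93,0.66,0.352,0.345,-1.99,1.42,0.324,0.318,-1.85,1.32,0.120,0.117,-2.50,1.79,0.177,0.180,1.69,1.19
S15,11.688,0.738,0.756,2.44,1.70,0.614,0.612,-0.33,0.23,0.354,0.348,-1.69,1.21,0.171,0.174,1.75,1.23,0.213,0.210,-1.41,1.00
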