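patient,vessel,group,dp_mbf_stress,dp_sd_stress,fermi_mbf_stress,fermi_sd_stress,dp_mpr,fermi_mpr
P1,LAD,3,0.82,0.28,1.68,0.60,0.88,1.54
P1,LCX,3,0.94,0.20,1.99,0.41,0.91,1.73
P1,RCA,2,0.84,0.17,1.77,0.79,0.91,1.77
P2,LAD,2,1.99,0.30,3.37,0.49,1.68,2.15
P2,LCX,2,1.98,0.27,2.61,0.41,1.26,1.87
P2,RCA,3,1.27,0.27,1.80,0.81,0.86,1.08
P3,LAD,2,1.20,0.10,1.19,0.34,0.71,0.78
P3,LCX,3,1.34,0.13,1.84,1.11,0.65,0.96
P3,RCA,2,1.58,0.31,1.18,0.16,0.81,0.70
P4,LAD,3,1.99,0.31,3.02,0.64,1.21,1.22
P4,LCX,3,1.61,0.73,1.98,0.58,0.90,1.05
P4,RCA,3,0.75,0.29,1.00,0.44,0.58,0.65
P5,LAD,1,2.86,0.59,3.26,0.88,3.26,3.37
P5,LCX,1,2.54,0.24,2.79,0.30,3.01,2.91
P5,RCA,1,2.60,0.36,2.88,0.33,2.68,3.04
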