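patient,hoffa_grade,effusion_grade,whole_knee_sum,severity_label,whole_knee_parse_confidence,peripatellar_ce,peripatellar_flair,volume_ce_cm3,volume_flair_cm3,wash_in_mean,wash_in_sd,wash_out_mean,wash_out_sd,ttp_mean,ttp_sd,pe_mean,pe_sd,iauc_mean,iauc_sd
1,1,3,11,moderate,reconstructed,3,2,14.74,11.59,1.12,0.81,0.17,0.24,1.04,0.44,0.93,1.49,0.67,0.53
2,1,2,12,moderate,reconstructed,4,4,13.61,10.47,0.67,0.41,0.42,0.36,0.93,0.68,1.68,1.12,0.69,0.55
3,1,2,18,severe,reconstructed,6,5,15.24,14.18,2.23,1.79,0.11,0.37,0.86,0.58,2.19,1.35,1.16,0.81
4,1,3,8,mild,reconstructed,3,2,12.98,10.01,1.06,1.02,0.19,0.38,0.96,0.3,2.56,2.94,1.09,1.55
5,2,3,18,severe,reconstructed,6,4,9.27,8.78,1.84,2.66,-0.02,0.5,0.93,0.38,1.78,1.89,0.82,1.07
6,3,2,6,mild,reconstructed,2,1,12.3,9.4,2.51,2.98,0.15,0.71,1.03,0.29,5.32,6.86,1.91,2.58
7,3,2,12,moderate,reconstructed,3,2,6.22,5.37,-0.25,1.59,0.68,0.39,1.29,0.51,3.36,3.68,0.88,1.02
8,1,3,6,mild,reconstructed,1,0,6.46,5.7,1.38,1.55,0.13,0.36,0.86,0.34,2.15,2.33,0.85,1.1
9,0,2,9,moderate,reconstructed,2,1,9.75,8.31,1.72,1.21,0.11,0.36,0.7,0.22,1.93,1.03,1.0,0.65
10,1,2,13,moderate,reconstructed,3,3,9.83,9.01,2.41,2.82,-0.01,0.59,0.63,0.12,2.55,2.49,1.69,2.2
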