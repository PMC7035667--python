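parameter,statistic,comparison,estimate,ci_low,ci_high
hoffa_synovitis,weighted_kappa,intra,0.76,0.45,1.05
hoffa_synovitis,weighted_kappa,inter,0.21,0.18,0.61
effusion_synovitis,weighted_kappa,intra,0.64,0.2,1.08
effusion_synovitis,weighted_kappa,inter,1.0,1.0,1.0
eleven_site_sum,weighted_kappa,intra,0.93,0.77,0.98
eleven_site_sum,weighted_kappa,inter,0.93,0.75,0.98
peripatellar_ce,weighted_kappa,intra,0.89,0.74,1.02
peripatellar_ce,weighted_kappa,inter,0.87,0.75,1.02
peripatellar_flair,weighted_kappa,intra,0.77,0.59,0.94
peripatellar_flair,weighted_kappa,inter,0.68,0.49,0.88
volume_ce,icc,intra,0.93,0.69,0.98
volume_ce,icc,inter,0.98,0.93,0.99
volume_flair,icc,intra,0.91,0.6,0.98
volume_flair,icc,inter,0.88,0.59,0.97
wash_in,icc,intra,0.97,0.99,0.99
wash_in,icc,inter,0.87,0.78,0.92
wash_out,icc,intra,0.95,0.89,0.97
wash_out,icc,inter,0.91,0.84,0.94
ttp,icc,intra,0.82,0.71,0.89
ttp,icc,inter,0.79,0.67,0.88
pe,icc,intra,0.99,0.98,0.99
pe,icc,inter,0.86,0.78,0.92
iauc,icc,intra,0.99,0.99,0.99
iauc,icc,inter,0.88,0.8,0.93
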