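parameter,value
theta_amplitude,7.86
theta_kout,2.78
theta_secretion_sd,0.182
theta_baseline,0.185
theta_a0,1.05
exp_amplitude,3.4
exp_secretion_sd,2.32
exp_baseline,4.29
tbw_reference,44.7
omega2_bov_amplitude,2.32
sigma2_prop,0.106
omega2_amplitude,0.22
omega2_kout,0.0699
omega2_secretion_sd,0.0715
omega2_baseline,0.406
omega2_a0,3.34
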