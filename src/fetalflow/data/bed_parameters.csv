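case,group,rp_mmhg_s_ml,cp_ml_mmhg
control,brain,33.87,0.0104
control,upper,46.44,0.0121
control,lungs,34.52,0.0049
control,peripheral,3.75,0.0602
control,coronary,68.75,
iugr_pedf,brain,50.90,0.0052
iugr_pedf,upper,74.20,0.0083
iugr_pedf,lungs,55.14,0.0038
iugr_pedf,peripheral,7.49,0.0242
iugr_pedf,coronary,109.33,
iugr_aedf,brain,60.39,0.0046
iugr_aedf,upper,88.04,0.0047
iugr_aedf,lungs,65.43,0.0055
iugr_aedf,peripheral,8.89,0.0208
iugr_aedf,coronary,130.31,
iugr_redf,brain,98.71,0.0024
iugr_redf,upper,143.89,0.0017
iugr_redf,lungs,106.93,0.0011
iugr_redf,peripheral,14.54,0.0049
iugr_redf,coronary,212.98,
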