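patient_id,gestational_age_wk,estimated_weight_g,heart_rate_bpm,aortic_peak_velocity_cm_s,pulmonary_peak_velocity_cm_s,aortic_valve_diameter_mm,pulmonary_valve_diameter_mm,pi_aoi,pi_ca,ifi,reversal_pct,pi_ratio_dao_ca,ua_edf
control,33.2,2250,128,91,67,6.0,6.6,3.39,2.82,1.36,3,1.10,present
iugr_pedf,33.6,1500,159,91,87,6.0,7.1,4.25,1.54,1.26,7,1.92,present
iugr_aedf,31.3,950,154,62,58,5.0,7.5,6.19,1.45,0.52,33,2.72,absent
iugr_redf,30.2,500,144,57,47,3.2,5.7,27.96,1.18,-12.36,91,5.14,reversed
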