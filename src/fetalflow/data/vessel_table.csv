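vessel_id,length_intercept_mm,length_slope_mm_per_week,diam_intercept_mm,diam_slope_mm_per_week,young_modulus_dyn_cm2
ascending_aorta,-8.61,0.88,-2.10,0.27,7.5e5
aortic_isthmus,-2.15,0.22,-1.86,0.19,7.5e5
descending_aorta,-34.25,3.57,-2.22,0.22,9.0e5
ductus_arteriosus,-2.41,0.31,-2.09,0.21,13.5e5
main_pulmonary_artery,-5.60,0.57,-2.77,0.30,7.5e5
right_pulmonary_artery,-4.00,0.41,-1.71,0.18,7.5e5
left_pulmonary_artery,-4.00,0.41,-1.95,0.19,7.5e5
brachiocephalic_trunk,-1.056,0.29,-1.78,0.18,7.5e5
left_subclavian_artery,-2.15,0.43,-1.22,0.12,9.0e5
right_subclavian_artery,-2.15,0.43,-1.22,0.12,9.0e5
left_common_carotid_artery,-9.69,1.59,-1.52,0.14,9.0e5
right_common_carotid_artery,-8.25,1.36,-1.52,0.14,9.0e5
left_internal_carotid_artery,-8.25,1.36,-1.22,0.11,13.5e5
right_internal_carotid_artery,-8.25,1.36,-1.22,0.11,13.5e5
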