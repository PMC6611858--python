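parameter,mean_mm,sd_mm
femur_width,72.28,8.92
femur_width2,54.00,5.83
femur_width3,39.01,3.85
femur_length,47.71,5.21
femur_length2,33.99,3.40
femur_length3,28.44,3.00
medial_radius,28.91,4.75
lateral_radius,26.09,4.21
posterior_radius,13.84,2.71
patella_radius,20.26,6.24
patella_curvature_radius,45.49,3.31
patella_height,19.09,2.46
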