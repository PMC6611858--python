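parameter,case1,case2,case3,case4,case5
femur_width,71.6,89.55,66,65.03,70.5
femur_width2,49.71,60.13,50.2,46,53.48
femur_width3,41.38,41.97,38.78,31.9,40.72
femur_length,52.74,48.28,51.25,39.09,47.01
femur_length2,32.42,40.16,31.3,30.95,33.05
femur_length3,28.75,33.47,25.35,28.66,25.4
medial_radius,27.43,36.94,29.56,27.57,22.28
lateral_radius,27.12,33.47,22.09,23.79,23.18
posterior_radius,14.07,11.2,12.43,14.73,12.09
patella_radius,19.01,20.32,17.12,16.54,32.23
patella_curvature_radius,44.94,51.24,42.41,43.51,43.17
patella_height,19.61,23.02,17.94,20.72,16.22
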