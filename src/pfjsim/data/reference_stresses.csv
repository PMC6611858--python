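model,angle_deg,mpfl_stress_mpa,lr_stress_mpa
native,0,8.85,1.52
native,30,0.78,0.15
native,60,0,0
native,90,0,0
native,120,0,0
anatomic,0,74.7,1.51
anatomic,30,26.55,0.14
anatomic,60,0,0
anatomic,90,0,0
anatomic,120,0,0
non_anatomic_physiometric,0,97.02,1.66
non_anatomic_physiometric,30,69.60,1.10
non_anatomic_physiometric,60,0,0
non_anatomic_physiometric,90,0,0
non_anatomic_physiometric,120,0,0
non_anatomic_non_physiometric,0,63.44,0.78
non_anatomic_non_physiometric,30,14.74,0.17
non_anatomic_non_physiometric,60,46.71,1.24
non_anatomic_non_physiometric,90,77.57,2.09
non_anatomic_non_physiometric,120,92.70,2.51
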