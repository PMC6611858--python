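model,angle_deg,peak_relative_pressure_mpa
native,0,0.18
native,30,0.016
anatomic,0,2.17
anatomic,30,0.14
non_anatomic_physiometric,0,2.77
non_anatomic_physiometric,30,1.91
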