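technique,angle_deg,length_mm,sd_mm,note
anatomic,0,60.2,6.1,b
anatomic,30,57.9,6.8,b
anatomic,40,57.7,6.0,
anatomic,60,57.3,6.4,a
anatomic,90,55.6,5.7,a
anatomic,120,50.7,4.9,a
non_anatomic_physiometric,0,51.6,4.6,b
non_anatomic_physiometric,30,50.8,5.4,b
non_anatomic_physiometric,40,48.8,5.0,
non_anatomic_physiometric,60,44.9,5.2,a
non_anatomic_physiometric,90,38.3,4.9,a
non_anatomic_physiometric,120,33.7,4.8,a
non_anatomic_non_physiometric,0,37.5,7.8,b
non_anatomic_non_physiometric,30,36.5,9.2,b
non_anatomic_non_physiometric,40,36.2,8.1,c
non_anatomic_non_physiometric,60,35.7,10.1,c
non_anatomic_non_physiometric,90,35.6,7.9,c
non_anatomic_non_physiometric,120,35.4,5.6,c
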