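case,angle_deg,mpfl_stress_mpa,lr_stress_mpa
1,60,59.03,1.62
1,90,119.20,5.38
1,120,252.00,7.06
2,60,19.51,4.56
2,90,29.52,7.54
2,120,34.7,8.37
3,0,12.28,8.22
3,30,3.93,2.68
4,0,60.02,1.15
4,30,29.47,0.79
5,0,40.24,0.53
5,30,70.30,1.27
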