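case,attachment,graft,bundle_config,bundle,angle_deg,length_mm,note
1,non_anatomic_non_satisfactory,semitendinosus_graft,SB,single,0,36.3,a
1,non_anatomic_non_satisfactory,semitendinosus_graft,SB,single,30,35.9,a
1,non_anatomic_non_satisfactory,semitendinosus_graft,SB,single,40,36.83,
1,non_anatomic_non_satisfactory,semitendinosus_graft,SB,single,60,38.7,b
1,non_anatomic_non_satisfactory,semitendinosus_graft,SB,single,90,43.7,b
1,non_anatomic_non_satisfactory,semitendinosus_graft,SB,single,120,46.3,b
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,proximal,0,23.1,a
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,proximal,30,33.3,a
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,proximal,40,36.33,b
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,proximal,60,42.4,b
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,proximal,90,46.6,b
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,proximal,120,48.6,b
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,distal,0,25.4,a
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,distal,30,39.7,a
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,distal,40,42.77,b
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,distal,60,48.9,b
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,distal,90,54.3,b
2,non_anatomic_non_satisfactory,semitendinosus_graft,DB,distal,120,54.8,b
3,non_anatomic_non_satisfactory,quadriceps_tendon_graft,SB,single,0,56.2,b
3,non_anatomic_non_satisfactory,quadriceps_tendon_graft,SB,single,30,46.8,b
3,non_anatomic_non_satisfactory,quadriceps_tendon_graft,SB,single,40,43.03,
3,non_anatomic_non_satisfactory,quadriceps_tendon_graft,SB,single,60,35.5,a
3,non_anatomic_non_satisfactory,quadriceps_tendon_graft,SB,single,90,24.2,a
3,non_anatomic_non_satisfactory,quadriceps_tendon_graft,SB,single,120,22.4,a
4,anatomic_satisfactory,semitendinosus_graft,DB,proximal,0,52.2,b
4,anatomic_satisfactory,semitendinosus_graft,DB,proximal,30,51.1,b
4,anatomic_satisfactory,semitendinosus_graft,DB,proximal,40,50.17,
4,anatomic_satisfactory,semitendinosus_graft,DB,proximal,60,48.3,a
4,anatomic_satisfactory,semitendinosus_graft,DB,proximal,90,41.3,a
4,anatomic_satisfactory,semitendinosus_graft,DB,proximal,120,35,a
4,anatomic_satisfactory,semitendinosus_graft,DB,distal,0,49.9,b
4,anatomic_satisfactory,semitendinosus_graft,DB,distal,30,49.7,b
4,anatomic_satisfactory,semitendinosus_graft,DB,distal,40,48.37,
4,anatomic_satisfactory,semitendinosus_graft,DB,distal,60,45.7,a
4,anatomic_satisfactory,semitendinosus_graft,DB,distal,90,39.7,a
4,anatomic_satisfactory,semitendinosus_graft,DB,distal,120,35.1,a
5,anatomic_satisfactory,semitendinosus_graft,DB,proximal,0,56.4,b
5,anatomic_satisfactory,semitendinosus_graft,DB,proximal,30,57,b
5,anatomic_satisfactory,semitendinosus_graft,DB,proximal,40,55.07,
5,anatomic_satisfactory,semitendinosus_graft,DB,proximal,60,51.2,a
5,anatomic_satisfactory,semitendinosus_graft,DB,proximal,90,46.9,a
5,anatomic_satisfactory,semitendinosus_graft,DB,proximal,120,42.3,a
5,anatomic_satisfactory,semitendinosus_graft,DB,distal,0,55.1,b
5,anatomic_satisfactory,semitendinosus_graft,DB,distal,30,56,b
5,anatomic_satisfactory,semitendinosus_graft,DB,distal,40,54.17,
5,anatomic_satisfactory,semitendinosus_graft,DB,distal,60,50.5,a
5,anatomic_satisfactory,semitendinosus_graft,DB,distal,90,45.8,a
5,anatomic_satisfactory,semitendinosus_graft,DB,distal,120,41.9,a
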