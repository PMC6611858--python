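tissue,stiffness_n_per_mm,poisson_ratio
quadriceps_tendon,1350,0.3
patellar_tendon,2000,0.3
lateral_retinaculum,2,0.3
native_mpfl,12,0.3
semitendinosus_graft,100,0.3
gracilis_graft,80,0.3
quadriceps_tendon_graft,33.6,0.3
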