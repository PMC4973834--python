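study_id,level_a,level_b,rho,cov
6,chalkley,all_vessels,0.55,
13,chalkley,all_vessels,0.74,
17,chalkley,all_vessels,0.27,
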