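study_id,level_a,level_b,rho,cov
1,3,6,0.589,
2,3,6,0.456,
3,3,6,0.580,
4,3,6,0.529,
5,3,6,0.613,
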