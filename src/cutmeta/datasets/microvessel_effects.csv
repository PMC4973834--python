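study_id,cutpoint,method,y,se,scale
1,,chalkley,0.122,0.087,log_hazard
3,,chalkley,0.039,0.06,log_hazard
4,,all_vessels,-0.02,0.09,log_hazard
5,,all_vessels,0.058,0.063,log_hazard
6,,chalkley,0.104,0.065,log_hazard
6,,all_vessels,0.02,0.091,log_hazard
7,,chalkley,0.039,0.038,log_hazard
8,,all_vessels,0.239,0.039,log_hazard
9,,all_vessels,-0.211,0.221,log_hazard
10,,all_vessels,0.03,0.061,log_hazard
11,,all_vessels,-0.01,0.02,log_hazard
12,,all_vessels,0.307,0.252,log_hazard
13,,chalkley,0.02,0.066,log_hazard
13,,all_vessels,0,0.025,log_hazard
14,,all_vessels,-0.693,0.758,log_hazard
15,,all_vessels,-0.174,0.142,log_hazard
16,,all_vessels,-0.02,0.025,log_hazard
17,,chalkley,0.03,0.047,log_hazard
17,,all_vessels,0.049,0.037,log_hazard
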