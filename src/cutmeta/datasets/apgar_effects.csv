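study_id,cutpoint,method,y,se,scale
1,3,,2.599,0.136,log_odds
1,6,,2.383,0.153,log_odds
2,3,,1.980,0.197,log_odds
2,6,,2.210,0.301,log_odds
3,3,,2.920,0.194,log_odds
3,6,,2.606,0.234,log_odds
4,3,,3.265,0.149,log_odds
4,6,,2.997,0.177,log_odds
5,3,,2.256,0.294,log_odds
5,6,,1.939,0.239,log_odds
6,3,,1.609,0.305,log_odds
7,3,,1.314,0.237,log_odds
8,3,,2.311,0.421,log_odds
9,3,,0.806,0.317,log_odds
10,6,,2.386,0.447,log_odds
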