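ga_min_weeks,ga_max_weeks,category,dose_mg_per_kg,interval_h
0,30,GA<30,15,36
30,,GA>=30,15,24
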