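pna_min_days,pna_max_days,weight_min_g,weight_max_g,category,dose_mg_per_kg,interval_h
0,14,0,800,1,16,48
0,14,800,1200,3,16,42
0,14,1200,2000,5,15,36
0,14,2000,2800,7,15,30
0,14,2800,,9,15,24
14,31,0,800,2,20,42
14,31,800,1200,4,20,36
14,31,1200,2000,6,18,30
14,31,2000,2800,8,18,24
14,31,2800,,10,18,20
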