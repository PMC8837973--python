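time_point_h,category,percent_of_dose,se
1.5,water_soluble_D9_derived,11.8,1.5
1.5,D9_phospholipid,15.3,1.4
1.5,D3_phospholipid,0.8,0.1
6,water_soluble_D9_derived,2.1,0.3
6,D9_phospholipid,10.6,1.1
6,D3_phospholipid,1.6,0.1
24,water_soluble_D9_derived,1.0,0.1
24,D9_phospholipid,9.7,1.1
24,D3_phospholipid,2.5,0.1
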