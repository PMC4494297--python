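region,scenario,value,units
east,s1,0.00,Tg CO2e
east,s2,0.19,Tg CO2e
east,s3,0.40,Tg CO2e
east,s4,0.50,Tg CO2e
west,s1,0.00,Tg CO2e
west,s2,0.29,Tg CO2e
west,s3,1.48,Tg CO2e
west,s4,1.81,Tg CO2e
canada,s1,0.00,Tg CO2e
canada,s2,0.48,Tg CO2e
canada,s3,1.88,Tg CO2e
canada,s4,2.31,Tg CO2e
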