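region,industry,variable,value,units
canada,all,total,53,Tg CO2e
canada,all,enteric,22,Tg CO2e
canada,beef,total,31,Tg CO2e
west,beef,total,26,Tg CO2e
west,beef,enteric,14,Tg CO2e
canada,dairy,total,10,Tg CO2e
canada,pork,total,7,Tg CO2e
canada,poultry,total,5,Tg CO2e
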