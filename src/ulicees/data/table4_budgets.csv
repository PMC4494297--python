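region,industry,section,gas,value,units
east,beef,baseline,ch4,2.64,Tg CO2e
east,beef,baseline,n2o,2.06,Tg CO2e
east,beef,baseline,co2,0.49,Tg CO2e
east,beef,baseline,total,5.19,Tg CO2e
west,beef,baseline,ch4,14.71,Tg CO2e
west,beef,baseline,n2o,8.32,Tg CO2e
west,beef,baseline,co2,2.78,Tg CO2e
west,beef,baseline,total,25.81,Tg CO2e
east,pork,baseline,ch4,1.62,Tg CO2e
east,pork,baseline,n2o,1.44,Tg CO2e
east,pork,baseline,co2,0.92,Tg CO2e
east,pork,baseline,total,3.99,Tg CO2e
west,pork,baseline,ch4,1.46,Tg CO2e
west,pork,baseline,n2o,0.77,Tg CO2e
west,pork,baseline,co2,0.83,Tg CO2e
west,pork,baseline,total,3.06,Tg CO2e
east,beef,deducted,ch4,0.26,Tg CO2e
east,beef,deducted,n2o,0.21,Tg CO2e
east,beef,deducted,co2,0.05,Tg CO2e
east,beef,deducted,total,0.52,Tg CO2e
west,beef,deducted,ch4,1.47,Tg CO2e
west,beef,deducted,n2o,0.83,Tg CO2e
west,beef,deducted,co2,0.28,Tg CO2e
west,beef,deducted,total,2.58,Tg CO2e
east,pork,additional,ch4,0.04,Tg CO2e
east,pork,additional,n2o,0.03,Tg CO2e
east,pork,additional,co2,0.02,Tg CO2e
east,pork,additional,total,0.09,Tg CO2e
west,pork,additional,ch4,0.26,Tg CO2e
west,pork,additional,n2o,0.14,Tg CO2e
west,pork,additional,co2,0.15,Tg CO2e
west,pork,additional,total,0.54,Tg CO2e
east,all,net,ch4,0.23,Tg CO2e
east,all,net,n2o,0.17,Tg CO2e
east,all,net,co2,0.03,Tg CO2e
east,all,net,total,0.43,Tg CO2e
west,all,net,ch4,1.21,Tg CO2e
west,all,net,n2o,0.69,Tg CO2e
west,all,net,co2,0.13,Tg CO2e
west,all,net,total,2.04,Tg CO2e
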