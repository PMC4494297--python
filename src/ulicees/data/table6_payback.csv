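region,scenario,variable,value,units
east,s1,soil_loss_40y,0.10,Tg CO2e
east,s2,soil_loss_40y,9.57,Tg CO2e
east,s3,soil_loss_40y,2.12,Tg CO2e
east,s4,soil_loss_40y,1.67,Tg CO2e
west,s1,soil_loss_40y,7.67,Tg CO2e
west,s2,soil_loss_40y,54.48,Tg CO2e
west,s3,soil_loss_40y,15.48,Tg CO2e
west,s4,soil_loss_40y,13.32,Tg CO2e
canada,s1,soil_loss_40y,7.77,Tg CO2e
canada,s2,soil_loss_40y,64.06,Tg CO2e
canada,s3,soil_loss_40y,17.60,Tg CO2e
canada,s4,soil_loss_40y,14.99,Tg CO2e
east,s1,decrease,0.43,Tg CO2e
east,s2,decrease,0.24,Tg CO2e
east,s3,decrease,0.02,Tg CO2e
east,s4,decrease,-0.08,Tg CO2e
west,s1,decrease,2.04,Tg CO2e
west,s2,decrease,1.75,Tg CO2e
west,s3,decrease,0.56,Tg CO2e
west,s4,decrease,0.23,Tg CO2e
canada,s1,decrease,2.46,Tg CO2e
canada,s2,decrease,2.02,Tg CO2e
canada,s3,decrease,0.59,Tg CO2e
canada,s4,decrease,0.15,Tg CO2e
east,s1,payback_years,0.2,y
east,s2,payback_years,40.1,y
east,s3,payback_years,92.7,y
east,s4,payback_years,,y
west,s1,payback_years,3.8,y
west,s2,payback_years,31.2,y
west,s3,payback_years,27.6,y
west,s4,payback_years,57,y
canada,s1,payback_years,3.2,y
canada,s2,payback_years,31.9,y
canada,s3,payback_years,29.9,y
canada,s4,payback_years,96.9,y
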