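region,variable,value,units
east,delta_c,1.1,kha
east,initial_freed,100.0,kha
east,delta_r,99.0,kha
east,annuals_s3,21.3,kha
east,annuals_s4,16.6,kha
west,delta_c,104.7,kha
west,initial_freed,494.4,kha
west,delta_r,389.7,kha
west,annuals_s3,106.5,kha
west,annuals_s4,77.1,kha
canada,delta_c,105.8,kha
canada,initial_freed,594.4,kha
canada,delta_r,488.6,kha
canada,annuals_s3,129.1,kha
canada,annuals_s4,93.4,kha
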