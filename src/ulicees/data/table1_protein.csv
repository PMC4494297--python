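region,industry,variable,value,units
east,beef,initial,36.9,kt
east,beef,reallocated,3.7,kt
east,beef,remaining,33.2,kt
east,beef,factor_pct,90,%
west,beef,initial,218.8,kt
west,beef,reallocated,21.9,kt
west,beef,remaining,197.0,kt
west,beef,factor_pct,90,%
east,pork,initial,157.7,kt
east,pork,reallocated,3.7,kt
east,pork,remaining,161.4,kt
east,pork,factor_pct,102,%
west,pork,initial,123.5,kt
west,pork,reallocated,21.9,kt
west,pork,remaining,145.4,kt
west,pork,factor_pct,118,%
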