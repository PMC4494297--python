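region,industry,crop_group,phase,value,units
east,beef,feed_grain,before,117,kha
east,beef,silage_corn,before,98,kha
east,beef,harvested_perennials,before,1000,kha
east,pork,feed_grain,before,1219,kha
west,beef,feed_grain,before,1818,kha
west,beef,silage_corn,before,42,kha
west,beef,harvested_perennials,before,4944,kha
west,pork,feed_grain,before,1641,kha
canada,beef,feed_grain,before,1994,kha
canada,beef,silage_corn,before,140,kha
canada,beef,harvested_perennials,before,5944,kha
canada,pork,feed_grain,before,2860,kha
east,beef,feed_grain,after,159,kha
east,beef,silage_corn,after,88,kha
east,beef,harvested_perennials,after,900,kha
east,pork,feed_grain,after,1247,kha
west,beef,feed_grain,after,1636,kha
west,beef,silage_corn,after,38,kha
west,beef,harvested_perennials,after,4449,kha
west,pork,feed_grain,after,1932,kha
canada,beef,feed_grain,after,1795,kha
canada,beef,silage_corn,after,126,kha
canada,beef,harvested_perennials,after,5350,kha
canada,pork,feed_grain,after,3179,kha
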