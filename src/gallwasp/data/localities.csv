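locality,latitude,longitude,elevation_m,annual_mean_c,life_cycle,flight,damage
Igualeja,36.617647,-5.135904,740,13.6,1,1,1
Jubrique,36.552279,-5.204078,789,15.7,0,1,0
Juzcar,36.623390,-5.165245,719,14.7,1,1,1
Ojen,36.577863,-4.884878,812,14.2,1,1,1
Parauta,36.667257,-5.113545,1049,13.1,0,1,0
Yunquera,36.720823,-4.954187,940,13.7,1,1,1
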