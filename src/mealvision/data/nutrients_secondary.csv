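fine_category,density_g_per_mL,kcal_per_100g,cho_g_per_100g,protein_g_per_100g,fat_g_per_100g,serving_volume_mL
rice soup,1.02,55,10,1.5,0.8,300
lasagna,0.85,135,13,8,6,280
meatball,0.95,215,9,16,13,120
green salad,0.35,17,3,1.2,0.2,150
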