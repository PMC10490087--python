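fine_category,density_g_per_mL,kcal_per_100g,cho_g_per_100g,protein_g_per_100g,fat_g_per_100g,serving_volume_mL
meatball,0.97,230,8,17,15,120
beef steak,1.04,220,0,31,10,180
pork chop,1.02,250,0,28,15,170
chicken breast,1.03,165,0,31,3.6,160
chicken nuggets,0.95,300,15,15,18,140
white bread,0.26,265,49,9,3.2,110
wholegrain bread,0.35,250,41,13,3.5,100
boiled potatoes,0.65,87,20,1.9,0.1,230
french fries,0.58,310,41,3.4,15,200
mashed potatoes,0.95,110,16,2,4,220
tap water,1.0,0,0,0,0,240
orange juice,1.04,45,10.4,0.7,0.2,240
whole milk,1.03,61,4.8,3.2,3.3,240
cola,1.04,42,10.6,0,0,330
chocolate cake,0.45,370,50,5,16,130
apple pie,0.6,240,34,2,11,150
apple,0.75,52,14,0.3,0.2,180
banana,0.94,89,23,1.1,0.3,130
olive oil,0.91,800,0,0,90,15
almonds,0.46,579,22,21,50,60
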